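"""Differential expression and marker statistics.

Between-group DE uses a two-sided Wilcoxon rank-sum test per gene on
normalized expression (assumption-light and standard for scRNA-seq), a
pseudocount-protected log2 fold change of group means, Benjamini-Hochberg
FDR, and percent-expressing per group; genes detected in under 1% of cells
of both groups are excluded from testing. Marker statistics cover
percent-expressing, any/all coexpression fractions ("expressed" = UMI count
> 0 throughout), a mid-rank detection percentile, and across-group
standardized (z-scored) mean expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "DEResult",
    "de_test",
    "percent_expressing",
    "coexpression_fraction",
    "detection_percentile",
    "standardized_marker_summary",
]


@dataclass
class DEResult:
    """Per-gene effect sizes, p-values, FDR and percent-expressing."""

    table: pd.DataFrame  # log2_fc, p_value, fdr, pct_expr_A, pct_expr_B, tested, direction
    group_a: str = "A"
    group_b: str = "B"

    def significant(self, fdr: float = 0.05, direction: str | None = None) -> pd.Index:
        t = self.table
        keep = t["tested"] & (t["fdr"] < fdr)
        if direction is not None:
            keep &= t["direction"] == direction
        return t.index[keep.fillna(False)]

    def write(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _cells_to_idx(cells: pd.Index, group) -> np.ndarray:
    """Cell selector: boolean mask, integer positions, or cell ids."""
    group = np.asarray(group)
    if group.dtype == bool:
        return np.flatnonzero(group)
    if np.issubdtype(group.dtype, np.integer):
        return group
    idx = cells.get_indexer(group)
    if (idx < 0).any():
        raise KeyError("unknown cell ids in group")
    return idx


def de_test(
    norm: NormalizedMatrix,
    group_a,
    group_b,
    pseudocount: float = 1e-2,
    min_detect_frac: float = 0.01,
    method: str = "wilcoxon",
    name_a: str = "A",
    name_b: str = "B",
) -> DEResult:
    """Two-group differential expression on normalized values.

    log2 fold change is log2((mean_A + pc) / (mean_B + pc)), positive when
    higher in group A. Genes expressed in fewer than ``min_detect_frac`` of
    cells in both groups are marked untested (p, fdr = NaN).
    """
    ia = _cells_to_idx(norm.cells, group_a)
    ib = _cells_to_idx(norm.cells, group_b)
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("both groups need at least 3 cells")
    if len(np.intersect1d(ia, ib)):
        raise ValueError("groups must be disjoint")
    A = np.asarray(norm.values[:, ia].todense())
    B = np.asarray(norm.values[:, ib].todense())
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    pct_a = 100.0 * (A > 0).mean(axis=1)
    pct_b = 100.0 * (B > 0).mean(axis=1)
    tested = (pct_a >= 100.0 * min_detect_frac) | (pct_b >= 100.0 * min_detect_frac)

    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    pvals = np.full(norm.n_genes, np.nan)
    if tested.any():
        if method == "wilcoxon":
            res = mannwhitneyu(
                A[tested], B[tested], axis=1, alternative="two-sided", method="asymptotic"
            )
        elif method == "ttest":
            res = ttest_ind(A[tested], B[tested], axis=1)
        else:
            raise ValueError(f"unknown method {method!r}")
        pvals[tested] = np.clip(res.pvalue, 0.0, 1.0)
    fdr = np.full(norm.n_genes, np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": pvals,
            "fdr": fdr,
            "pct_expr_A": pct_a,
            "pct_expr_B": pct_b,
            "tested": tested,
            "direction": np.where(lfc > 0, f"up_{name_a}", np.where(lfc < 0, f"up_{name_b}", "none")),
        },
        index=norm.genes,
    )
    return DEResult(table, name_a, name_b)


def _panel_rows(matrix: CountMatrix, symbols) -> tuple[list[str], list[int], list[str]]:
    sym2row = matrix.symbol_to_rows()
    present, rows, absent = [], [], []
    for s in symbols:
        if s in sym2row:
            present.append(s)
            rows.append(sym2row[s])
        else:
            absent.append(s)
    return present, rows, absent


def percent_expressing(matrix: CountMatrix, symbols, group=None) -> pd.Series:
    """Percent of group cells with count > 0 per panel gene.

    Genes absent from the annotation are reported as NaN (absent), never 0.
    """
    sub = matrix if group is None else matrix.subset_cells(
        np.asarray(group) if np.asarray(group).dtype == bool else group
    )
    if sub.n_cells == 0:
        raise ValueError("group is empty")
    present, rows, absent = _panel_rows(sub, symbols)
    pct = pd.Series(np.nan, index=pd.Index(symbols, name="symbol"), name="pct_expressing")
    if rows:
        det = np.asarray((sub.counts[rows] > 0).mean(axis=1)).ravel()
        pct.loc[present] = 100.0 * det
    return pct


def coexpression_fraction(matrix: CountMatrix, symbols, mode: str = "any", group=None) -> float:
    """Percent of cells expressing >= 1 (``any``) or all (``all``) panel genes."""
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    sub = matrix if group is None else matrix.subset_cells(
        np.asarray(group) if np.asarray(group).dtype == bool else group
    )
    present, rows, absent = _panel_rows(sub, symbols)
    if not rows:
        raise ValueError(f"no panel gene present in the matrix: {list(symbols)}")
    det = np.asarray((sub.counts[rows] > 0).todense())
    hit = det.any(axis=0) if mode == "any" else det.all(axis=0)
    return float(100.0 * hit.mean())


def detection_percentile(matrix: CountMatrix, symbol: str) -> dict:
    """Detection-count percentile of one gene among all genes (mid-rank).

    percentile = 100 * (n_lower + 0.5 * n_ties_excluding_self) / (n_genes - 1).
    Returns the raw detection count, the number of genes detected in
    strictly fewer cells, and the percentile.
    """
    sym2row = matrix.symbol_to_rows()
    if symbol not in sym2row:
        raise KeyError(f"gene {symbol!r} not present")
    det = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    q = det[sym2row[symbol]]
    n_lower = int((det < q).sum())
    n_ties = int((det == q).sum()) - 1
    n = len(det)
    pct = 100.0 * (n_lower + 0.5 * n_ties) / (n - 1) if n > 1 else 100.0
    return {
        "symbol": symbol,
        "detection_count": int(q),
        "n_genes_lower": n_lower,
        "percentile": pct,
        "n_genes": n,
    }


def standardized_marker_summary(
    norm: NormalizedMatrix, symbols, groups: dict[str, object], gene_symbols: pd.Series | None = None
) -> pd.DataFrame:
    """Across-group z-scores of panel-gene mean expression (gene x group).

    ``groups`` maps group name -> cell ids or boolean mask. Genes constant
    across groups get an all-zero row. ``gene_symbols`` maps the normalized
    matrix's gene ids to symbols when they differ.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if gene_symbols is None:
        gene_symbols = pd.Series(norm.genes, index=norm.genes)
    sym2idx: dict[str, int] = {}
    for i, s in enumerate(gene_symbols.reindex(norm.genes)):
        sym2idx.setdefault(str(s), i)
    rows = [sym2idx[s] for s in symbols if s in sym2idx]
    names = [s for s in symbols if s in sym2idx]
    means = np.empty((len(rows), len(groups)))
    for j, members in enumerate(groups.values()):
        idx = _cells_to_idx(norm.cells, members)
        means[:, j] = np.asarray(norm.values[rows][:, idx].mean(axis=1)).ravel()
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=pd.Index(names, name="symbol"), columns=list(groups))
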