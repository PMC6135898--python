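"""Cell and gene quality-control filtering.

Cells are flagged on three criteria — high/low total counts (the proxy for
mapped reads when starting from a count matrix), high mitochondrial
percentage and high ribosomal percentage — using either robust
median +/- k*MAD rules (default) or absolute thresholds; the union of flags
is removed. Genes detected in less than a configurable fraction of the
surviving cells (default 0.1%) are then removed, matching the study's
filtering order: cells first, then genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import log
from .containers import CountMatrix

__all__ = ["QCPolicy", "QCReport", "compute_cell_qc", "flag_cells", "filter_genes", "run_qc"]

CRITERIA = ("reads_outlier", "mito_high", "ribo_high")


@dataclass
class QCPolicy:
    """Thresholding policy for the three cell-level criteria.

    Each criterion uses its MAD multiplier unless the corresponding absolute
    bound(s) are given. Reads are judged two-sided on log10(total + 1)
    (capturing both low and high outliers); mito and ribo are one-sided high
    on percentages.
    """

    reads_mad_k: float = 3.0
    mito_mad_k: float = 3.0
    ribo_mad_k: float = 3.0
    reads_log10_bounds: tuple[float, float] | None = None  # absolute (lo, hi)
    mito_pct_max: float | None = None  # absolute, strict >
    ribo_pct_max: float | None = None


@dataclass
class QCReport:
    """Bookkeeping of one cell-filtering pass."""

    flags: pd.DataFrame  # boolean per cell per criterion + 'fail' union
    counts_per_criterion: dict[str, int]
    union_count: int
    n_cells_before: int
    n_cells_after: int
    thresholds: dict[str, object]
    warnings: list[str] = field(default_factory=list)
    n_genes_before: int | None = None
    n_genes_removed: int | None = None
    n_genes_after: int | None = None

    def summary(self) -> dict:
        return {
            "n_cells_before": self.n_cells_before,
            "counts_per_criterion": self.counts_per_criterion,
            "union_count": self.union_count,
            "n_cells_after": self.n_cells_after,
            "n_genes_before": self.n_genes_before,
            "n_genes_removed": self.n_genes_removed,
            "n_genes_after": self.n_genes_after,
            "thresholds": self.thresholds,
            "warnings": self.warnings,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.flags.reset_index().to_csv(outdir / "qc_flags.tsv", sep="\t", index=False)
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=str)


def compute_cell_qc(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: total counts, genes detected, mito%, ribo%.

    All-zero cells get 0 percentages; they are caught downstream as reads
    outliers.
    """
    counts = matrix.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_det = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[matrix.genes["is_mito"].to_numpy()].sum(axis=0)).ravel()
    ribo = np.asarray(counts[matrix.genes["is_ribo"].to_numpy()].sum(axis=0)).ravel()
    safe = np.maximum(total, 1)
    return pd.DataFrame(
        {
            "total_counts": total.astype(int),
            "n_genes_detected": n_det.astype(int),
            "pct_mito": 100.0 * mito / safe,
            "pct_ribo": 100.0 * ribo / safe,
        },
        index=matrix.cell_ids,
    )


def _mad_bounds(values: np.ndarray, k: float, two_sided: bool, warnings: list[str], name: str):
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    if mad <= 0:
        warnings.append(f"{name}: MAD is zero (constant metric); criterion flags nothing")
        return None
    lo = med - k * mad if two_sided else -np.inf
    return (lo, med + k * mad)


def flag_cells(qc: pd.DataFrame, policy: QCPolicy | None = None) -> QCReport:
    """Flag cells failing any criterion and report per-criterion counts."""
    policy = policy or QCPolicy()
    warnings: list[str] = []
    thresholds: dict[str, object] = {}

    log_tot = np.log10(qc["total_counts"].to_numpy() + 1.0)
    if policy.reads_log10_bounds is not None:
        bounds = tuple(map(float, policy.reads_log10_bounds))
        thresholds["reads_log10_bounds"] = bounds
    else:
        bounds = _mad_bounds(log_tot, policy.reads_mad_k, True, warnings, "reads")
        thresholds["reads_log10_bounds"] = bounds
        thresholds["reads_rule"] = f"median +/- {policy.reads_mad_k}*MAD (log10 totals)"
    if bounds is None:
        reads_flag = np.zeros(len(qc), bool)
    else:
        reads_flag = (log_tot < bounds[0]) | (log_tot > bounds[1])
    reads_flag |= qc["total_counts"].to_numpy() == 0  # empty cells always fail

    flags = {"reads_outlier": reads_flag}
    for crit, col, abs_thr, k in (
        ("mito_high", "pct_mito", policy.mito_pct_max, policy.mito_mad_k),
        ("ribo_high", "pct_ribo", policy.ribo_pct_max, policy.ribo_mad_k),
    ):
        vals = qc[col].to_numpy()
        if abs_thr is not None:
            thr = float(abs_thr)
            thresholds[f"{col}_max"] = thr
        else:
            b = _mad_bounds(vals, k, False, warnings, crit)
            thr = None if b is None else b[1]
            thresholds[f"{col}_max"] = thr
            thresholds[f"{crit}_rule"] = f"median + {k}*MAD"
        flags[crit] = np.zeros(len(qc), bool) if thr is None else vals > thr

    fl = pd.DataFrame(flags, index=qc.index)
    fl["fail"] = fl[list(CRITERIA)].any(axis=1)
    counts = {c: int(fl[c].sum()) for c in CRITERIA}
    union = int(fl["fail"].sum())
    report = QCReport(
        flags=fl,
        counts_per_criterion=counts,
        union_count=union,
        n_cells_before=len(qc),
        n_cells_after=len(qc) - union,
        thresholds=thresholds,
        warnings=warnings,
    )
    log.info(
        "flagged cells: reads %d, mito %d, ribo %d, union %d of %d",
        counts["reads_outlier"], counts["mito_high"], counts["ribo_high"], union, len(qc),
    )
    return report


def filter_genes(
    matrix: CountMatrix, min_cell_fraction: float = 0.001
) -> tuple[CountMatrix, int]:
    """Remove genes detected in less than ``min_cell_fraction`` of cells.

    A gene is kept iff its detection count (cells with count > 0) is at
    least ``min_cell_fraction * n_cells``; the strict "less than" removal
    mirrors the 0.1%-of-cells rule. Apply after cell filtering.
    """
    if not (0 <= min_cell_fraction < 1):
        raise ValueError("min_cell_fraction must be in [0, 1)")
    det = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    keep = det >= min_cell_fraction * matrix.n_cells
    n_removed = int((~keep).sum())
    return matrix.subset_genes(keep), n_removed


def run_qc(
    matrix: CountMatrix,
    policy: QCPolicy | None = None,
    min_cell_fraction: float = 0.001,
) -> tuple[CountMatrix, QCReport]:
    """Full QC pass: flag + drop cells, then drop under-detected genes."""
    qc = compute_cell_qc(matrix)
    report = flag_cells(qc, policy)
    kept = matrix.subset_cells(~report.flags["fail"].to_numpy())
    report.n_genes_before = matrix.n_genes
    filtered, n_removed = filter_genes(kept, min_cell_fraction)
    report.n_genes_removed = n_removed
    report.n_genes_after = filtered.n_genes
    log.info(
        "QC: %d -> %d cells; %d -> %d genes",
        report.n_cells_before, report.n_cells_after,
        report.n_genes_before, report.n_genes_after,
    )
    return filtered, report
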