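"""Dropout-aware clustering of cells into subpopulations.

The route mirrors CIDR (Clustering through Imputation and Dimensionality
Reduction): library-size normalization to log2(1 + CPM); a per-cell
dropout-candidate threshold from the first minimum of a kernel density
estimate of nonzero expression; a logistic dropout-probability curve fitted
to per-gene candidate rates; a pairwise "implicitly imputed" squared
dissimilarity; principal-coordinate embedding; and Ward hierarchical
clustering with a stability-plateau choice of the cluster number, after
which subpopulations are renamed 1..K in decreasing size order. A
bin-matched control-gene score assigns cell-cycle phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.linalg import eigh
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.metrics import adjusted_rand_score

from ._utils import log, stream
from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "normalize",
    "DropoutModel",
    "fit_dropout_model",
    "cidr_dissimilarity",
    "Embedding",
    "pcoa",
    "ClusterResult",
    "cluster_cells",
    "rank_subpopulations",
    "score_cell_cycle",
    "cluster_pipeline",
]


def normalize(matrix: CountMatrix, scale: float = 1e6) -> NormalizedMatrix:
    """log2(1 + count * scale / column_total); zero counts stay exactly 0."""
    counts = matrix.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals <= 0).any():
        raise ValueError(
            "zero-total cells present; run QC cell filtering before normalizing"
        )
    vals = counts.multiply(scale / totals[None, :]).tocsr()
    vals.data = np.log2(1.0 + vals.data)
    labels = matrix.cells["sample"] if "sample" in matrix.cells.columns else None
    return NormalizedMatrix(vals, matrix.gene_ids, matrix.cell_ids, scale, labels)


# ---------------------------------------------------------------------------
# dropout model
# ---------------------------------------------------------------------------

@dataclass
class DropoutModel:
    """Per-cell candidate thresholds plus a fitted logistic dropout curve.

    ``P(u) = 1 / (1 + exp(a * (u - b)))`` is the probability that an entry
    at expression level u (log2 scale) is a dropout; it is monotone
    decreasing for a > 0.
    """

    thresholds: np.ndarray  # log2 units, one per cell
    a: float = 1.0
    b: float = 2.0
    warnings: list[str] = field(default_factory=list)

    def prob(self, u: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(np.clip(self.a * (u - self.b), -500, 500)))

    def candidates(self, values: np.ndarray) -> np.ndarray:
        """Boolean genes x cells mask of dropout candidates (value below the
        cell's threshold, zeros included)."""
        return values < self.thresholds[None, :]


def _first_kde_minimum(
    vals: np.ndarray,
    n_grid: int = 256,
    valley_depth: float = 0.5,
    min_low_mass: float = 0.02,
) -> float | None:
    """Density minimum between the first two genuine modes of a KDE.

    A pair of modes counts as genuine bimodality only when the valley
    between them drops below ``valley_depth`` times the lower of the two
    mode densities (KDE wiggles on a unimodal profile never dip that far)
    and each side of the valley carries at least ``min_low_mass`` of the
    values (a lone outlier is not a mode). Returns None when no such pair
    exists.
    """
    if len(vals) < 5 or np.ptp(vals) <= 0:
        return None
    try:
        kde = gaussian_kde(vals, bw_method="silverman")
    except np.linalg.LinAlgError:
        return None
    grid = np.linspace(vals.min(), vals.max(), n_grid)
    dens = kde(grid)
    padded = np.concatenate(([0.0], dens, [0.0]))
    peaks = find_peaks(padded)[0] - 1  # endpoints may be modes
    for i in range(len(peaks) - 1):
        lo, hi = peaks[i], peaks[i + 1]
        v = lo + int(np.argmin(dens[lo : hi + 1]))
        deep = dens[v] < valley_depth * min(dens[lo], dens[hi])
        frac_low = float(np.mean(vals <= grid[v]))
        if deep and min_low_mass <= frac_low <= 1.0 - min_low_mass:
            return float(grid[v])
    return None


def fit_dropout_model(
    norm: NormalizedMatrix,
    default_params: tuple[float, float] = (1.0, 2.0),
) -> DropoutModel:
    """Fit per-cell dropout thresholds and the shared logistic curve.

    Each cell's candidate threshold is the first local minimum of a KDE of
    its full log-expression profile, zeros included: the zero spike forms
    the dropout mode and the threshold is the density minimum separating it
    from the expressed mode. Cells with a unimodal density fall back to the
    median threshold of the other cells; if no cell is bimodal the data are
    treated as dropout-free (threshold 0, so no entry is a candidate).
    The per-gene candidate rate is then regressed on mean nonzero
    expression by least squares on the logistic curve.
    """
    warnings: list[str] = []
    if norm.n_cells < 100:
        warnings.append(f"only {norm.n_cells} cells; dropout fit may be unstable")
    dense = norm.dense()
    thr = np.full(norm.n_cells, np.nan)
    for j in range(norm.n_cells):
        t = _first_kde_minimum(dense[:, j])
        if t is not None:
            thr[j] = t
    found = ~np.isnan(thr)
    if not found.any():
        warnings.append("no bimodal cell found; treating data as dropout-free")
        thr[:] = 0.0
    else:
        thr[~found] = np.median(thr[found])

    model = DropoutModel(thresholds=thr, warnings=warnings)
    cand = model.candidates(dense)
    rate = cand.mean(axis=1)
    with np.errstate(invalid="ignore"):
        nz_mean = np.where(
            (dense > 0).sum(axis=1) > 0,
            dense.sum(axis=1) / np.maximum((dense > 0).sum(axis=1), 1),
            np.nan,
        )
    ok = ~np.isnan(nz_mean)
    try:
        if ok.sum() < 10:
            raise RuntimeError("too few genes with nonzero expression")
        (a, b), _ = curve_fit(
            lambda u, a, b: 1.0 / (1.0 + np.exp(np.clip(a * (u - b), -500, 500))),
            nz_mean[ok],
            rate[ok],
            p0=(1.0, float(np.median(nz_mean[ok]))),
            bounds=((1e-3, -50.0), (50.0, 50.0)),
            maxfev=10000,
        )
        model.a, model.b = float(a), float(b)
    except Exception as exc:  # degenerate data: keep the documented default
        model.a, model.b = default_params
        model.warnings.append(f"logistic fit failed ({exc}); using default (a, b)")
        log.warning("dropout curve fit failed; falling back to default parameters")
    return model


# ---------------------------------------------------------------------------
# dissimilarity and embedding
# ---------------------------------------------------------------------------

def cidr_dissimilarity(norm: NormalizedMatrix, model: DropoutModel) -> np.ndarray:
    """Pairwise dissimilarity with implicit pairwise dropout imputation.

    For a gene with values (u, v) in cells (i, j): if neither value is a
    dropout candidate the gene contributes (u - v)^2; if exactly one is
    (say u), it is imputed as P(v) * u + (1 - P(v)) * v, contributing
    P(v)^2 * (u - v)^2; if both are candidates the gene contributes 0.
    D(i, j) is the square root of the summed contributions. The stored
    expression matrix is never modified.
    """
    Z = norm.dense()
    C = model.candidates(Z)
    W = model.prob(Z)  # dropout prob at the observed value
    M = (~C).astype(float)
    # neither-candidate term: sum over g of m_i m_j (u - v)^2
    N1 = M * Z
    N2 = M * Z * Z
    D2 = M.T @ N2 + N2.T @ M - 2.0 * (N1.T @ N1)
    # one-candidate term (i candidate, j not): weight P(v_j)^2
    Q = M * W * W
    Qv = Q * Z
    Qv2 = Q * Z * Z
    Cf = C.astype(float)
    T = (Cf * Z * Z).T @ Q - 2.0 * (Cf * Z).T @ Qv + Cf.T @ Qv2
    D2 += T + T.T
    np.fill_diagonal(D2, 0.0)
    D = np.sqrt(np.clip(D2, 0.0, None))
    return (D + D.T) / 2.0


@dataclass
class Embedding:
    """Principal-coordinate embedding with its eigenvalue diagnostics."""

    coords: np.ndarray  # cells x D
    eigenvalues: np.ndarray  # all eigenvalues, descending
    n_negative: int
    cells: pd.Index | None = None
    warnings: list[str] = field(default_factory=list)


def pcoa(dissimilarity: np.ndarray, n_dims: int = 4, cells: pd.Index | None = None) -> Embedding:
    """Classical multidimensional scaling of a dissimilarity matrix.

    Eigendecomposition of the double-centered squared-dissimilarity matrix;
    coordinates are returned for the top ``n_dims`` positive eigenvalues,
    truncating (with a warning) if fewer are positive. Negative eigenvalues
    (non-Euclidean input) are dropped and counted.
    """
    D = np.asarray(dissimilarity, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity must be square and symmetric")
    n = D.shape[0]
    D2 = D * D
    rowm = D2.mean(axis=1)
    B = -0.5 * (D2 - rowm[:, None] - rowm[None, :] + D2.mean())
    w, V = eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(abs(w[0]), 1.0) * 1e-12
    n_pos = int((w > tol).sum())
    n_neg = int((w < -tol).sum())
    warnings = []
    keep = min(n_dims, n_pos)
    if keep < n_dims:
        warnings.append(
            f"requested {n_dims} dims but only {n_pos} positive eigenvalues; truncated"
        )
    coords = V[:, :keep] * np.sqrt(w[:keep])[None, :] if keep else np.zeros((n, 0))
    return Embedding(coords, w, n_neg, cells=cells, warnings=warnings)


# ---------------------------------------------------------------------------
# stability-selected hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Ward dendrogram, stability trace and size-ranked labels."""

    labels: pd.Series  # subpopulation id per cell, 1..K, size-ranked
    linkage: np.ndarray
    stability: pd.DataFrame  # per window: height, n_clusters, ARI to previous
    selected_k: int
    plateau_length: int = 0  # windows in the selected stability run
    embedding: Embedding | None = None

    def newick(self) -> str:
        """Dendrogram as a Newick string on cell-id leaves."""
        tree = sch.to_tree(self.linkage)
        names = list(self.labels.index)

        def rec(node):
            if node.is_leaf():
                return f"{names[node.id]}:{node.dist:.6g}"
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return f"({rec(tree.left)},{rec(tree.right)});"


def rank_subpopulations(labels: np.ndarray | pd.Series) -> np.ndarray:
    """Relabel clusters 1..K so sizes are non-increasing.

    Ties are broken by original label order, so the mapping is deterministic
    and idempotent on already-ranked labels.
    """
    arr = np.asarray(labels)
    uniq, counts = np.unique(arr, return_counts=True)
    order = np.lexsort((uniq, -counts))  # size desc, then original label asc
    mapping = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([mapping[int(v)] for v in arr])


def cluster_cells(
    embedding: Embedding,
    max_k: int = 10,
    n_windows: int = 40,
) -> ClusterResult:
    """Ward clustering with a stability-plateau choice of cluster number.

    The dendrogram is cut at ``n_windows`` evenly spaced heights spanning
    the tree; adjacent partitions are compared by adjusted Rand index and
    the cluster count (restricted to <= max_k) persisting over the longest
    run of consecutive windows is selected, ties broken toward fewer
    clusters. Labels are then renamed in decreasing size order.
    """
    coords = embedding.coords
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 cells to cluster")
    if coords.shape[1] < 2:
        log.warning("clustering on a %d-dim embedding", coords.shape[1])
    Zl = sch.linkage(coords, method="ward")
    hmax = Zl[-1, 2]
    heights = np.linspace(0.0, hmax, n_windows + 1)[1:]  # exclude 0, include top
    parts = [sch.fcluster(Zl, h, criterion="distance") for h in heights]
    ks = np.array([len(np.unique(p)) for p in parts])
    ari = np.array(
        [np.nan]
        + [adjusted_rand_score(parts[i - 1], parts[i]) for i in range(1, len(parts))]
    )
    stability = pd.DataFrame(
        {"height": heights, "n_clusters": ks, "ari_to_previous": ari}
    )

    # longest run of a constant admissible cluster count
    best_k, best_len = None, -1
    i = 0
    while i < len(ks):
        j = i
        while j + 1 < len(ks) and ks[j + 1] == ks[i]:
            j += 1
        run = j - i + 1
        k = int(ks[i])
        if k <= max_k and (
            run > best_len or (run == best_len and k < (best_k or np.inf))
        ):
            best_k, best_len = k, run
        i = j + 1
    if best_k is None:  # every window produced more than max_k clusters
        best_k = max_k
        labels_raw = sch.fcluster(Zl, best_k, criterion="maxclust")
    else:
        w = int(np.flatnonzero(ks == best_k)[0])
        labels_raw = parts[w]
    ranked = rank_subpopulations(labels_raw)
    index = embedding.cells if embedding.cells is not None else pd.RangeIndex(len(ranked))
    log.info("selected k=%d (plateau of %d/%d windows)", best_k, best_len, n_windows)
    return ClusterResult(
        labels=pd.Series(ranked, index=index, name="subpop"),
        linkage=Zl,
        stability=stability,
        selected_k=int(best_k),
        plateau_length=max(best_len, 0),
        embedding=embedding,
    )


def cluster_pipeline(
    matrix: CountMatrix,
    n_dims: int = 4,
    max_k: int = 10,
    n_windows: int = 40,
    scale: float = 1e6,
) -> tuple[ClusterResult, NormalizedMatrix, DropoutModel]:
    """normalize -> dropout model -> CIDR dissimilarity -> PCoA -> cluster."""
    norm = normalize(matrix, scale=scale)
    model = fit_dropout_model(norm)
    D = cidr_dissimilarity(norm, model)
    emb = pcoa(D, n_dims=n_dims, cells=norm.cells)
    return cluster_cells(emb, max_k=max_k, n_windows=n_windows), norm, model


# ---------------------------------------------------------------------------
# cell-cycle scoring
# ---------------------------------------------------------------------------

def score_cell_cycle(
    norm: NormalizedMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign G1/S/G2M phases from bin-matched control-gene scores.

    Per cell, the S score is the mean expression of the S markers minus the
    mean of control genes drawn (``n_ctrl`` per marker) from the marker's
    average-expression bin among ``n_bins`` bins; G2M analogously. Phase is
    G1 when both scores are <= 0, otherwise the argmax score.
    """
    gidx = {g: i for i, g in enumerate(norm.genes)}
    s_rows = [gidx[g] for g in s_genes if g in gidx]
    g2m_rows = [gidx[g] for g in g2m_genes if g in gidx]
    for name, rows, markers in (("s_genes", s_rows, s_genes), ("g2m_genes", g2m_rows, g2m_genes)):
        if not rows:
            raise ValueError(
                f"none of the {name} are present in the matrix: {sorted(markers)[:10]}"
            )
    dense = norm.dense()
    avg = dense.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), int)
    bin_of[order] = np.minimum(
        (np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1
    )
    rng = stream(seed, "generic")
    bins = [np.flatnonzero(bin_of == bq) for bq in range(n_bins)]

    def score(rows: list[int]) -> np.ndarray:
        ctrl: list[int] = []
        for r in rows:
            pool = bins[bin_of[r]]
            take = rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False)
            ctrl.extend(int(t) for t in take)
        return dense[rows].mean(axis=0) - dense[sorted(set(ctrl))].mean(axis=0)

    s_score = score(s_rows)
    g2m_score = score(g2m_rows)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=norm.cells,
    )
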