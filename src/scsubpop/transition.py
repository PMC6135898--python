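"""Subpopulation transition/similarity scoring across samples.

In the scGPS lineage, subpopulations found independently in two samples are
compared by training, for each target subpopulation, an ensemble of
bootstrap L1-penalized logistic one-vs-rest classifiers on the target
sample, then scoring every source-sample cell: one-vs-rest probabilities
are renormalized into conditional class probabilities, each cell is
assigned to its argmax class, and entry (s, t) of the transition matrix is
the percent of source-subpopulation-s cells assigned to target class t
(mean and sd over bootstraps; rows of means sum to 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from ._utils import child_seed, log, stream
from .containers import NormalizedMatrix
from .de import DEResult

__all__ = [
    "select_features",
    "TransitionModel",
    "train_transition_model",
    "TransitionMatrix",
    "score_transitions",
]


def select_features(de_results: dict[object, DEResult] | DEResult, top_n: int = 50) -> list[str]:
    """Union of the top ``top_n`` genes per subpopulation contrast.

    Genes are ranked by FDR, then by decreasing |log2FC|, with ties broken
    by gene id, so the list is deterministic.
    """
    if isinstance(de_results, DEResult):
        de_results = {0: de_results}
    features: set[str] = set()
    for de in de_results.values():
        t = de.table[de.table["tested"]].copy()
        t["abs_lfc"] = t["log2_fc"].abs()
        t = t.sort_values(
            by=["fdr", "abs_lfc"],
            ascending=[True, False],
            kind="mergesort",
        )
        # mergesort is stable; pre-sort by gene id for a deterministic tie-break
        t = t.loc[t.index.sort_values()].sort_values(
            by=["fdr", "abs_lfc"], ascending=[True, False], kind="mergesort"
        )
        features.update(t.index[:top_n])
    return sorted(features)


@dataclass
class TransitionModel:
    """Bootstrap ensembles of one-vs-rest penalized classifiers."""

    target_name: str
    classes: list[int]  # target subpopulation labels
    features: list[str]
    ensembles: dict[int, list]  # class -> list of fitted models (one per bootstrap)
    bootstrap_cells: dict[int, list[np.ndarray]]  # class -> per-bootstrap cell indices

    @property
    def n_bootstraps(self) -> int:
        return len(next(iter(self.ensembles.values())))


def _feature_matrix(norm: NormalizedMatrix, features: list[str]) -> np.ndarray:
    idx = pd.Index(norm.genes).get_indexer(features)
    missing = [f for f, i in zip(features, idx) if i < 0]
    X = np.zeros((norm.n_cells, len(features)))
    present = idx >= 0
    if present.any():
        X[:, present] = np.asarray(norm.values[idx[present]].todense()).T
    if missing:
        log.warning("%d feature genes absent from matrix, imputed as 0", len(missing))
    return X


def train_transition_model(
    norm_target: NormalizedMatrix,
    labels_target,
    features: list[str],
    n_bootstraps: int = 50,
    subsample_frac: float = 0.8,
    seed: int = 0,
    target_name: str = "target",
    cv_folds: int = 5,
) -> TransitionModel:
    """Train the per-subpopulation bootstrap classifier ensembles.

    For each target subpopulation and bootstrap, a stratified
    ``subsample_frac`` of the target cells is drawn and an L1-penalized
    logistic one-vs-rest model is fitted on the feature genes, with the
    penalty chosen by internal stratified cross-validation.
    """
    y = np.asarray(labels_target)
    classes = sorted(int(c) for c in np.unique(y))
    counts = {c: int((y == c).sum()) for c in classes}
    for c, n in counts.items():
        if n < 3:
            raise ValueError(f"subpopulation {c} has only {n} cells (< 3)")
        if n < 20:
            log.warning("subpopulation %s has only %d cells", c, n)
    X = _feature_matrix(norm_target, features)
    rng = stream(seed, "generic")
    ensembles: dict[int, list] = {c: [] for c in classes}
    boots: dict[int, list[np.ndarray]] = {c: [] for c in classes}
    for b in range(n_bootstraps):
        # one stratified subsample per bootstrap, shared across classes
        take: list[np.ndarray] = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            k = max(2, int(round(subsample_frac * len(idx))))
            take.append(rng.choice(idx, size=min(k, len(idx)), replace=False))
        sub = np.sort(np.concatenate(take))
        for c in classes:
            yb = (y[sub] == c).astype(int)
            model = LogisticRegressionCV(
                Cs=np.logspace(-2, 2, 5),
                cv=StratifiedKFold(
                    n_splits=cv_folds, shuffle=True, random_state=child_seed(seed, 1000 + b)
                ),
                l1_ratios=(1.0,),  # pure L1 penalty
                solver="liblinear",
                scoring="accuracy",
                max_iter=1000,
                random_state=child_seed(seed, 2000 + b),
                use_legacy_attributes=False,
            )
            model.fit(X[sub], yb)
            ensembles[c].append(model)
            boots[c].append(sub)
    return TransitionModel(target_name, classes, list(features), ensembles, boots)


@dataclass
class TransitionMatrix:
    """Source x target subpopulation similarity percentages."""

    mean: pd.DataFrame  # rows source subpops, cols target subpops; sums to 100/row
    sd: pd.DataFrame
    n_bootstraps: int
    per_cell_probability: pd.DataFrame | None = None  # bootstrap-averaged

    def write(self, path) -> None:
        rows = []
        for s in self.mean.index:
            for t in self.mean.columns:
                rows.append((s, t, self.mean.loc[s, t], self.sd.loc[s, t], self.n_bootstraps))
        pd.DataFrame(
            rows,
            columns=["source_subpop", "target_subpop", "mean_pct", "sd_pct", "n_bootstraps"],
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def score_transitions(
    model: TransitionModel,
    norm_source: NormalizedMatrix,
    labels_source,
) -> TransitionMatrix:
    """Score source cells against a trained target model.

    Per bootstrap, each source cell gets renormalized class probabilities
    and an argmax assignment; entry (s, t) is the percent of source
    subpopulation s assigned to target class t, averaged over bootstraps.
    """
    y = np.asarray(labels_source)
    src_classes = sorted(int(c) for c in np.unique(y))
    X = _feature_matrix(norm_source, model.features)
    n_boot = model.n_bootstraps
    tallies = np.zeros((n_boot, len(src_classes), len(model.classes)))
    prob_sum = np.zeros((X.shape[0], len(model.classes)))
    for b in range(n_boot):
        raw = np.column_stack(
            [model.ensembles[c][b].predict_proba(X)[:, 1] for c in model.classes]
        )
        prob = raw / np.maximum(raw.sum(axis=1, keepdims=True), 1e-300)
        prob_sum += prob
        assigned = np.argmax(prob, axis=1)
        for si, s in enumerate(src_classes):
            mask = y == s
            for ti in range(len(model.classes)):
                tallies[b, si, ti] = 100.0 * np.mean(assigned[mask] == ti)
    mean = pd.DataFrame(
        tallies.mean(axis=0), index=src_classes, columns=model.classes
    )
    sd = pd.DataFrame(tallies.std(axis=0, ddof=1) if n_boot > 1 else np.zeros_like(tallies[0]),
                      index=src_classes, columns=model.classes)
    mean.index.name = sd.index.name = "source_subpop"
    mean.columns.name = sd.columns.name = "target_subpop"
    per_cell = pd.DataFrame(
        prob_sum / n_boot, index=norm_source.cells, columns=model.classes
    )
    return TransitionMatrix(mean, sd, n_boot, per_cell)
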