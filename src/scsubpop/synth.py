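"""Synthetic pooled-iPSC scRNA-seq experiment generator.

Emulates the data structure of a two-donor x two-media pooled 10x
experiment: zero-inflated negative-binomial UMI counts over ~16k expressed
genes, a shared latent subpopulation structure with one dominant and one
minor subpopulation, mitochondrial / ribosomal gene content, cell-cycle
programs, donor-distinguishing SNP genotypes and per-cell allele counts,
plus optionally planted QC failures and rare genes so every downstream
filter can be checked against known truth.

All randomness flows from a single master seed through fixed per-component
streams (gene params, cell assignment, counts, dropout, QC planting,
genotypes, alleles, cycle), so the same config is bit-reproducible and
changing one component (e.g. the SNP panel) never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from ._utils import log, stream
from .containers import CountMatrix

__all__ = [
    "QCPlant",
    "SimConfig",
    "simulate_experiment",
    "simulate_genotypes",
    "simulate_allele_counts",
    "write_experiment",
]

_MEDIA_NAMES = ("SF", "E8")
_BLOCK = 512  # cells generated per dense block (fixed => reproducible)

# Planted-failure severities; far from baseline so absolute QC thresholds
# separate planted from natural cells with overwhelming probability.
_PLANT_MITO_SHARE = 0.45
_PLANT_RIBO_SHARE = 0.65
_PLANT_LOW_FACTOR = 0.02
_PLANT_HIGH_FACTOR = 25


@dataclass
class QCPlant:
    """Numbers of cells planted to fail each QC criterion.

    ``double`` cells are counted inside both ``reads`` and ``mito`` (they
    fail the two criteria at once), so the expected union is
    reads + mito + ribo - double.
    """

    reads: int = 0
    mito: int = 0
    ribo: int = 0
    double: int = 0

    @property
    def union(self) -> int:
        return self.reads + self.mito + self.ribo - self.double


@dataclass
class SimConfig:
    """Parameters of one synthetic pooled experiment.

    Defaults state the emulated study design: 2 donors x 2 media with
    ~5k cells per sample and ~16k expressed genes; three latent
    subpopulations with the first dominant (60/25/15%); 50 marker genes per
    subpopulation shifted by 2 on the log2 scale; NB dispersion 0.3 with a
    shared logistic dropout curve on log2(1+CPM) (midpoint 4, steepness 1)
    giving a median gene detection rate near 30% of cells at a mean library
    of 8,000 UMIs (the study reports under 20,000 UMIs per cell).
    """

    n_donors: int = 2
    n_media: int = 2
    cells_per_sample: int = 5000
    n_genes: int = 16000
    subpop_proportions: Sequence[float] = (0.60, 0.25, 0.15)
    n_marker_genes_per_subpop: int = 50
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    dropout_midpoint: float = 4.0
    dropout_steepness: float = 1.0
    frac_mito_genes: float = 0.01
    frac_ribo_genes: float = 0.05
    n_snps: int = 200
    allele_depth_mean: float = 20.0
    seq_error: float = 0.01
    planted_qc_failures: QCPlant = field(default_factory=QCPlant)
    planted_rare_genes: int = 0
    seed: int = 0
    # secondary knobs (documented defaults, rarely changed)
    mean_library_size: float = 8000.0
    library_sdlog: float = 0.35
    gene_meanlog: float = 0.0
    gene_sdlog: float = 0.6
    mito_share: float = 0.06
    ribo_share: float = 0.20
    cycle_fractions: Sequence[float] = (0.60, 0.20, 0.20)  # G1, S, G2M
    n_cycle_genes: int = 30
    cycle_log2fc: float = 1.5
    discriminating_snps: bool = False

    def validate(self) -> None:
        props = np.asarray(self.subpop_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subpop_proportions must sum to 1 within 1e-9")
        if (props <= 0).any():
            raise ValueError("subpop_proportions must all be > 0")
        if self.frac_mito_genes + self.frac_ribo_genes >= 1:
            raise ValueError("frac_mito_genes + frac_ribo_genes must be < 1")
        k = len(props)
        n_special = (
            int(round(self.frac_mito_genes * self.n_genes))
            + int(round(self.frac_ribo_genes * self.n_genes))
            + k * self.n_marker_genes_per_subpop
            + 2 * self.n_cycle_genes
            + self.planted_rare_genes
        )
        if n_special >= self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_special} special genes"
            )
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_proportions)

    @property
    def samples(self) -> list[tuple[str, str]]:
        donors = [f"D{i + 1}" for i in range(self.n_donors)]
        media = [
            _MEDIA_NAMES[j] if j < len(_MEDIA_NAMES) else f"M{j + 1}"
            for j in range(self.n_media)
        ]
        return [(d, m) for d in donors for m in media]


def _dropout_prob(rel_expr: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    """Extra-zero probability as a function of relative expression.

    The curve lives on the log2(1 + CPM) scale, the same scale the CIDR-style
    imputation model is fitted on; relative expression p is the gene's share
    of a cell's library, so CPM = 1e6 * p.
    """
    u = np.log2(1.0 + 1e6 * rel_expr)
    return expit(-steepness * (u - midpoint))


def _make_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    n_mito = int(round(cfg.frac_mito_genes * n))
    n_ribo = int(round(cfg.frac_ribo_genes * n))
    idx_all = rng.permutation(n)
    mito_idx = np.sort(idx_all[:n_mito])
    ribo_idx = np.sort(idx_all[n_mito : n_mito + n_ribo])

    # Baseline relative expression; floored so every gene is "reliably
    # detected" (the matrix emulates the post-filter gene universe).
    x = rng.lognormal(cfg.gene_meanlog, cfg.gene_sdlog, n)
    floor = 0.2 * x.sum() / cfg.mean_library_size  # >= ~0.2 expected counts
    x = np.maximum(x, floor)

    # Scale mito/ribo genes to hit the configured library shares.
    other = np.ones(n, bool)
    other[mito_idx] = False
    other[ribo_idx] = False
    rest_share = 1.0 - cfg.mito_share - cfg.ribo_share
    for idx, share in ((mito_idx, cfg.mito_share), (ribo_idx, cfg.ribo_share)):
        if len(idx):
            x[idx] *= share / rest_share * x[other].sum() / x[idx].sum()

    is_mito = np.zeros(n, bool)
    is_mito[mito_idx] = True
    is_ribo = np.zeros(n, bool)
    is_ribo[ribo_idx] = True
    symbols = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    symbols[mito_idx] = [f"MT-G{i:04d}" for i in range(n_mito)]
    symbols[ribo_idx] = [
        f"{'RPL' if i % 2 else 'RPS'}{i:04d}" for i in range(n_ribo)
    ]
    genes = pd.DataFrame(
        {
            "symbol": symbols,
            "is_mito": is_mito,
            "is_ribo": is_ribo,
            "base_rel_expr": x,
        },
        index=pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id"),
    )

    # Assign marker / cycle-program / rare genes among plain genes.
    plain = np.flatnonzero(other)
    picked = rng.permutation(plain)
    k = cfg.n_subpops
    pos = 0
    marker_of = np.zeros(n, int)  # 0 = none, else subpopulation label
    for s in range(1, k + 1):
        sel = picked[pos : pos + cfg.n_marker_genes_per_subpop]
        marker_of[sel] = s
        pos += cfg.n_marker_genes_per_subpop
    program = np.array([""] * n, dtype=object)
    program[picked[pos : pos + cfg.n_cycle_genes]] = "S"
    pos += cfg.n_cycle_genes
    program[picked[pos : pos + cfg.n_cycle_genes]] = "G2M"
    pos += cfg.n_cycle_genes
    rare = np.zeros(n, bool)
    rare[picked[pos : pos + cfg.planted_rare_genes]] = True
    genes["marker_subpop"] = marker_of
    genes["cycle_program"] = program
    genes["planted_rare"] = rare
    return genes


def _plant_assignments(cfg: SimConfig, n_cells: int, rng: np.random.Generator):
    """Choose which global cell indices fail which planted QC criteria."""
    plant = cfg.planted_qc_failures
    need = plant.union
    if need == 0:
        return {}
    if need > n_cells:
        raise ValueError("more planted QC failures than cells")
    pool = rng.choice(n_cells, size=need, replace=False)
    fails: dict[int, list[str]] = {}
    i = 0
    for _ in range(plant.double):
        fails[int(pool[i])] = ["reads", "mito"]
        i += 1
    for _ in range(plant.reads - plant.double):
        fails[int(pool[i])] = ["reads"]
        i += 1
    for _ in range(plant.mito - plant.double):
        fails[int(pool[i])] = ["mito"]
        i += 1
    for _ in range(plant.ribo):
        fails[int(pool[i])] = ["ribo"]
        i += 1
    return fails


def simulate_experiment(cfg: SimConfig):
    """Generate one synthetic experiment.

    Returns
    -------
    matrix : CountMatrix
        Genes x cells UMI counts with annotation and sample labels.
    truth : pandas.DataFrame
        Per-cell ground truth (donor, medium, sample, subpop, planted QC
        failures, cycle phase), indexed by cell id.
    genotypes : pandas.DataFrame
        SNP x donor alt-allele dosage in {0, 1, 2}.
    alleles : pandas.DataFrame
        Long table of per-cell per-SNP ref/alt read counts.
    """
    cfg.validate()
    rng_genes = stream(cfg.seed, "genes")
    rng_cells = stream(cfg.seed, "cells")
    rng_counts = stream(cfg.seed, "counts")
    rng_drop = stream(cfg.seed, "dropout")
    rng_plant = stream(cfg.seed, "qc_plant")
    rng_cycle = stream(cfg.seed, "cycle")

    genes = _make_genes(cfg, rng_genes)
    k = cfg.n_subpops
    x = genes["base_rel_expr"].to_numpy()
    marker_of = genes["marker_subpop"].to_numpy()
    program = genes["cycle_program"].to_numpy()
    # per-subpopulation expression profiles (relative weights)
    profiles = np.tile(x[:, None], (1, k))
    for s in range(1, k + 1):
        profiles[marker_of == s, s - 1] *= 2.0**cfg.marker_log2fc
    cyc_mult = {"G1": np.ones(cfg.n_genes)}
    for ph in ("S", "G2M"):
        m = np.ones(cfg.n_genes)
        m[program == ph] = 2.0**cfg.cycle_log2fc
        cyc_mult[ph] = m

    samples = cfg.samples
    n_cells = cfg.cells_per_sample * len(samples)

    # per-cell latent assignments
    props = np.asarray(cfg.subpop_proportions, float)
    subpop = rng_cells.choice(k, size=n_cells, p=props) + 1
    lib_mu = np.log(cfg.mean_library_size) - cfg.library_sdlog**2 / 2
    libsize = rng_cells.lognormal(lib_mu, cfg.library_sdlog, n_cells)
    phases = np.asarray(["G1", "S", "G2M"], dtype=object)[
        rng_cycle.choice(3, size=n_cells, p=np.asarray(cfg.cycle_fractions, float))
    ]
    planted = _plant_assignments(cfg, n_cells, rng_plant)

    mito_rows = np.flatnonzero(genes["is_mito"].to_numpy())
    ribo_rows = np.flatnonzero(genes["is_ribo"].to_numpy())
    rare_rows = np.flatnonzero(genes["planted_rare"].to_numpy())
    rare_cells = (
        rng_plant.choice(n_cells, size=len(rare_rows), replace=True)
        if len(rare_rows)
        else np.array([], int)
    )

    blocks = []
    for start in range(0, n_cells, _BLOCK):
        stop = min(start + _BLOCK, n_cells)
        b = stop - start
        prof = profiles[:, subpop[start:stop] - 1]  # genes x b
        mult = np.stack([cyc_mult[ph] for ph in phases[start:stop]], axis=1)
        rel = prof * mult
        rel /= rel.sum(axis=0, keepdims=True)
        mu = rel * libsize[start:stop][None, :]
        lam = rng_counts.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion)
        counts = rng_counts.poisson(lam).astype(np.int64)
        pdrop = _dropout_prob(rel, cfg.dropout_midpoint, cfg.dropout_steepness)
        counts[rng_drop.random(size=counts.shape) < pdrop] = 0
        if len(rare_rows):
            counts[rare_rows, :] = 0
        # planted QC failures (cells processed in global order within block)
        for ci in range(start, stop):
            crit = planted.get(ci)
            if not crit:
                continue
            col = counts[:, ci - start]
            if "mito" in crit:
                _inflate_share(col, mito_rows, _PLANT_MITO_SHARE, rng_plant)
            if "ribo" in crit:
                _inflate_share(col, ribo_rows, _PLANT_RIBO_SHARE, rng_plant)
            if "reads" in crit:
                # alternate low/high by global index parity
                if ci % 2 == 0:
                    col[:] = rng_plant.binomial(col, _PLANT_LOW_FACTOR)
                else:
                    col *= _PLANT_HIGH_FACTOR
        blocks.append(sp.csc_matrix(counts))
    counts = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((cfg.n_genes, 0))
    counts = sp.lil_matrix(counts)
    for g, c in zip(rare_rows, rare_cells):
        counts[g, c] = 1  # rare gene detected in exactly one cell
    counts = sp.csr_matrix(counts)

    cell_ids = pd.Index(
        [f"CELL{i:06d}" for i in range(n_cells)], name="cell_id"
    )
    donor = np.empty(n_cells, object)
    medium = np.empty(n_cells, object)
    sample = np.empty(n_cells, object)
    for si, (d, m) in enumerate(samples):
        sl = slice(si * cfg.cells_per_sample, (si + 1) * cfg.cells_per_sample)
        donor[sl], medium[sl], sample[sl] = d, m, f"{d}_{m}"
    truth = pd.DataFrame(
        {
            "donor": donor,
            "medium": medium,
            "sample": sample,
            "subpop": subpop,
            "planted_qc_fail": [
                ",".join(planted.get(i, [])) for i in range(n_cells)
            ],
            "cycle_phase": phases,
        },
        index=cell_ids,
    )
    cells = truth[["sample", "donor", "medium"]].copy()
    matrix = CountMatrix(counts, genes, cells)

    genotypes = simulate_genotypes(
        cfg.n_snps,
        [f"D{i + 1}" for i in range(cfg.n_donors)],
        seed=cfg.seed,
        discriminating=cfg.discriminating_snps,
    )
    alleles = simulate_allele_counts(
        genotypes, truth, cfg.allele_depth_mean, cfg.seq_error, cfg.seed
    )
    log.info(
        "simulated %d cells x %d genes in %d samples", n_cells, cfg.n_genes, len(samples)
    )
    return matrix, truth, genotypes, alleles


def _inflate_share(col: np.ndarray, rows: np.ndarray, share: float, rng) -> None:
    """Add counts on ``rows`` so their library share reaches ``share``."""
    total = max(int(col.sum()), 1)
    current = int(col[rows].sum())
    extra = int(np.ceil(max(0.0, (share * total - current) / (1.0 - share))))
    if extra <= 0 or not len(rows):
        return
    w = col[rows].astype(float) + 1.0
    col[rows] += rng.multinomial(extra, w / w.sum())


def simulate_genotypes(
    n_snps: int,
    donors: Sequence[str],
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    discriminating: bool = False,
) -> pd.DataFrame:
    """Draw SNP x donor alt-allele dosages under Hardy-Weinberg sampling.

    With ``discriminating=True`` every SNP is redrawn until at least two
    donors differ, giving a fully informative panel.
    """
    rng = stream(seed, "genotypes")
    rows = []
    for _ in range(n_snps):
        while True:
            maf = rng.uniform(*maf_range)
            g = rng.binomial(2, maf, size=len(donors))
            if not discriminating or len(set(g)) > 1:
                rows.append(g)
                break
    gt = pd.DataFrame(
        np.array(rows, dtype=int),
        index=pd.Index([f"SNP{i:04d}" for i in range(n_snps)], name="snp_id"),
        columns=list(donors),
    )
    return gt


def simulate_allele_counts(
    genotypes: pd.DataFrame,
    truth: pd.DataFrame,
    depth: float,
    error: float,
    seed: int,
) -> pd.DataFrame:
    """Per-cell per-SNP read counts given each cell's true donor.

    Total reads at a SNP are Poisson(depth / n_snps); alt reads are
    Binomial(total, p_g) with p_0 = error, p_1 = 0.5, p_2 = 1 - error where
    g is the genotype of the cell's donor. Rows with zero reads are omitted.
    """
    if not (0 <= error < 0.5):
        raise ValueError("error must be in [0, 0.5)")
    rng = stream(seed, "alleles")
    n_snps = len(genotypes)
    p_of = np.array([error, 0.5, 1.0 - error])
    recs = []
    snp_ids = genotypes.index.to_numpy()
    for cell_id, row in truth.iterrows():
        g = genotypes[row["donor"]].to_numpy()
        tot = rng.poisson(depth / n_snps, size=n_snps)
        cov = tot > 0
        if not cov.any():
            continue
        alt = rng.binomial(tot[cov], p_of[g[cov]])
        for s, t, a in zip(snp_ids[cov], tot[cov], alt):
            recs.append((cell_id, s, int(t - a), int(a)))
    return pd.DataFrame(recs, columns=["cell_id", "snp_id", "ref_count", "alt_count"])


def write_experiment(
    outdir: str | Path,
    matrix: CountMatrix,
    truth: pd.DataFrame,
    genotypes: pd.DataFrame,
    alleles: pd.DataFrame,
) -> None:
    """Write the 10x-style triplet plus truth/genotypes/allele tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.write_mtx_dir(outdir)
    truth.reset_index().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    genotypes.reset_index().to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    alleles.to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
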