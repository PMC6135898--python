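"""Generator contracts: determinism, planted truth, marginal statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scsubpop.synth import (
    QCPlant,
    SimConfig,
    simulate_allele_counts,
    simulate_experiment,
    simulate_genotypes,
    write_experiment,
)

SMALL = dict(n_donors=1, n_media=1, n_snps=5, n_marker_genes_per_subpop=10, n_cycle_genes=5)


def test_seed_determinism(tmp_path):
    """Same config (incl. seed) gives bit-identical outputs, on disk too."""
    cfg = SimConfig(cells_per_sample=150, n_genes=200, seed=1, **SMALL)
    out = [simulate_experiment(cfg) for _ in range(2)]
    (m1, t1, g1, a1), (m2, t2, g2, a2) = out
    assert (m1.counts != m2.counts).nnz == 0
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(g1, g2)
    pd.testing.assert_frame_equal(a1, a2)
    for i, (m, t, g, a) in enumerate(out):
        write_experiment(tmp_path / str(i), m, t, g, a)
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "truth.tsv", "allele_counts.tsv"):
        assert (tmp_path / "0" / name).read_bytes() == (tmp_path / "1" / name).read_bytes()


def test_subpop_proportions_multinomial_envelope():
    """Planted label counts fall in the 99% multinomial envelope of
    (1200, 500, 300) at 2,000 cells."""
    cfg = SimConfig(
        cells_per_sample=2000, n_genes=200, subpop_proportions=(0.6, 0.25, 0.15), seed=3, **SMALL
    )
    _, truth, _, _ = simulate_experiment(cfg)
    counts = truth["subpop"].value_counts()
    for k, p in zip((1, 2, 3), (0.6, 0.25, 0.15)):
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, p)
        assert lo <= counts[k] <= hi


def test_dropout_only_adds_zeros():
    """Observed zero fraction >= NB-only zero fraction for every gene."""
    base = dict(cells_per_sample=400, n_genes=300, seed=5, **SMALL)
    m_on, *_ = simulate_experiment(SimConfig(**base))
    m_off, *_ = simulate_experiment(SimConfig(dropout_midpoint=-50.0, **base))
    on = np.asarray(m_on.counts.todense())
    off = np.asarray(m_off.counts.todense())
    # entrywise: dropout either keeps the count or zeroes it
    assert np.all((on == off) | (on == 0))
    zero_on = (on == 0).mean(axis=1)
    zero_off = (off == 0).mean(axis=1)
    assert np.all(zero_on >= zero_off)
    assert zero_on.mean() > zero_off.mean()  # dropout is actually active


def test_marginal_means_converge():
    """Without dropout and shifts, empirical gene means approach the drawn
    baseline means (relative error < 5% at 10,000 cells)."""
    cfg = SimConfig(
        cells_per_sample=10000, n_genes=300, marker_log2fc=0.0, cycle_log2fc=0.0,
        dropout_midpoint=-50.0, seed=6, **SMALL
    )
    m, *_ = simulate_experiment(cfg)
    x = m.genes["base_rel_expr"].to_numpy()
    expected = x / x.sum() * cfg.mean_library_size
    observed = np.asarray(m.counts.mean(axis=1)).ravel()
    big = expected >= 0.3
    assert big.sum() > 100
    rel = np.abs(observed[big] - expected[big]) / expected[big]
    assert rel.max() < 0.05


def test_planted_qc_truth_bookkeeping():
    """Planted failure lists respect the double-failure overlap."""
    cfg = SimConfig(
        cells_per_sample=500, n_genes=200, seed=8,
        planted_qc_failures=QCPlant(reads=12, mito=20, ribo=6, double=4), **SMALL
    )
    _, truth, _, _ = simulate_experiment(cfg)
    fail = truth["planted_qc_fail"]
    has = {c: fail.str.contains(c).to_numpy() for c in ("reads", "mito", "ribo")}
    assert has["reads"].sum() == 12
    assert has["mito"].sum() == 20
    assert has["ribo"].sum() == 6
    assert (has["reads"] & has["mito"]).sum() == 4
    assert (fail != "").sum() == 12 + 20 + 6 - 4


@pytest.mark.parametrize(
    "bad",
    [
        dict(subpop_proportions=(0.5, 0.4)),  # does not sum to 1
        dict(n_genes=30),  # too small for special genes
        dict(seq_error=0.7),
        dict(nb_dispersion=0.0),
    ],
)
def test_invalid_config_rejected(bad):
    cfg = SimConfig(**{"cells_per_sample": 50, "n_genes": 200, **SMALL, **bad})
    with pytest.raises(ValueError):
        cfg.validate()


def test_allele_counts_noiseless_homozygote():
    """error=0 with genotype 2 at every SNP gives pure alt reads."""
    gt = pd.DataFrame(
        {"D1": [2, 2, 2], "D2": [0, 0, 0]},
        index=pd.Index(["S1", "S2", "S3"], name="snp_id"),
    )
    truth = pd.DataFrame(
        {"donor": ["D1"] * 50}, index=pd.Index([f"c{i}" for i in range(50)], name="cell_id")
    )
    al = simulate_allele_counts(gt, truth, depth=30.0, error=0.0, seed=1)
    assert len(al) > 0
    assert (al["ref_count"] == 0).all()


def test_allele_counts_het_frequency():
    """Genotype 1 at high depth gives alt fraction near 0.5 (binomial CI)."""
    gt = pd.DataFrame({"D1": [1], "D2": [1]}, index=pd.Index(["S1"], name="snp_id"))
    truth = pd.DataFrame(
        {"donor": ["D1"] * 200}, index=pd.Index([f"c{i}" for i in range(200)], name="cell_id")
    )
    al = simulate_allele_counts(gt, truth, depth=100.0, error=0.0, seed=2)
    tot = int((al["ref_count"] + al["alt_count"]).sum())
    alt = int(al["alt_count"].sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], tot, 0.5)
    assert lo <= alt <= hi


def test_allele_counts_error_bounds():
    gt = pd.DataFrame({"D1": [1]}, index=pd.Index(["S1"], name="snp_id"))
    truth = pd.DataFrame({"donor": ["D1"]}, index=pd.Index(["c0"], name="cell_id"))
    with pytest.raises(ValueError):
        simulate_allele_counts(gt, truth, depth=10.0, error=0.6, seed=0)


def test_discriminating_genotypes():
    gt = simulate_genotypes(100, ["A", "B"], seed=4, discriminating=True)
    assert (gt["A"] != gt["B"]).all()
    assert set(np.unique(gt.to_numpy())) <= {0, 1, 2}
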