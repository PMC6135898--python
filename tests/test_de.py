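"""Differential expression and marker statistics."""

import numpy as np
import pandas as pd
import pytest

from scsubpop.cluster import normalize
from scsubpop.de import (
    coexpression_fraction,
    de_test,
    detection_percentile,
    percent_expressing,
    standardized_marker_summary,
)
from scsubpop.synth import SimConfig, simulate_experiment

from conftest import make_count_matrix, make_norm


@pytest.fixture(scope="module")
def two_group_norm():
    """1,000 cells in two planted groups with 2-fold markers (log2FC 1)."""
    cfg = SimConfig(
        n_donors=1, n_media=1, cells_per_sample=1000, n_genes=2000, n_snps=5,
        subpop_proportions=(0.5, 0.5), marker_log2fc=1.0, n_cycle_genes=5, seed=12,
    )
    m, truth, _, _ = simulate_experiment(cfg)
    return m, truth, normalize(m)


def test_identical_groups_zero_log2fc():
    rng = np.random.default_rng(0)
    dense = rng.poisson(3, (50, 20)) + 1.0
    norm = make_norm(np.hstack([dense, dense]))  # B duplicates A
    res = de_test(norm, np.arange(20), np.arange(20, 40))
    assert np.allclose(res.table["log2_fc"], 0.0)


def test_antisymmetry(two_group_norm):
    _, truth, norm = two_group_norm
    g1 = (truth["subpop"] == 1).to_numpy()
    ab = de_test(norm, g1, ~g1)
    ba = de_test(norm, ~g1, g1)
    assert np.allclose(ab.table["log2_fc"], -ba.table["log2_fc"])


def test_power_on_planted_two_fold_markers(two_group_norm):
    m, truth, norm = two_group_norm
    g1 = (truth["subpop"] == 1).to_numpy()
    res = de_test(norm, g1, ~g1)
    planted = m.gene_ids[m.genes["marker_subpop"] > 0]
    sig = res.significant(0.05)
    assert np.isin(planted, sig).mean() >= 0.95


def test_bh_fdr_monotone_in_pvalue_rank(two_group_norm):
    _, truth, norm = two_group_norm
    g1 = (truth["subpop"] == 1).to_numpy()
    t = de_test(norm, g1, ~g1).table
    t = t[t["tested"]].sort_values("p_value")
    assert t["fdr"].is_monotonic_increasing
    assert (t["fdr"] >= t["p_value"] - 1e-12).all()


def test_overlapping_or_tiny_groups_rejected(two_group_norm):
    _, _, norm = two_group_norm
    with pytest.raises(ValueError, match="disjoint"):
        de_test(norm, np.arange(10), np.arange(5, 15))
    with pytest.raises(ValueError, match="3 cells"):
        de_test(norm, np.arange(2), np.arange(10, 20))


def test_prefilter_marks_undetected_genes_untested():
    dense = np.ones((2, 400))
    dense[1] = 0.0
    dense[1, 0] = 1.0  # detected in 1 of 400 cells: < 1% in both groups
    res = de_test(make_norm(dense), np.arange(200), np.arange(200, 400))
    assert res.table["tested"].tolist() == [True, False]
    assert np.isnan(res.table["p_value"].iloc[1])


# -- percent expressing / coexpression ------------------------------------

def test_percent_expressing_semantics():
    m = make_count_matrix(
        [[1, 2, 3, 4], [0, 0, 0, 5]], symbols=["UBIQ", "RARE"]
    )
    pct = percent_expressing(m, ["UBIQ", "RARE", "MISSING"])
    assert pct["UBIQ"] == 100.0
    assert pct["RARE"] == 25.0
    assert np.isnan(pct["MISSING"])  # absent, not zero


def test_percent_expressing_planted_fraction():
    """Gene planted at exactly 905/5000 detections reads 18.1%."""
    dense = np.zeros((2, 5000))
    dense[0, :905] = 1
    dense[1, :] = 1
    pct = percent_expressing(make_count_matrix(dense, symbols=["NANOG", "OTHER"]), ["NANOG"])
    assert pct["NANOG"] == pytest.approx(18.1)


def test_coexpression_modes_and_dominance():
    rng = np.random.default_rng(1)
    dense = (rng.random((3, 4000)) < np.array([[0.6], [0.5], [0.4]])).astype(int)
    m = make_count_matrix(dense, symbols=["A", "B", "C"])
    any_pct = coexpression_fraction(m, ["A", "B", "C"], "any")
    all_pct = coexpression_fraction(m, ["A", "B", "C"], "all")
    singles = percent_expressing(m, ["A", "B", "C"])
    assert all_pct <= any_pct
    assert any_pct >= singles.max()
    # independent detection: expect 1 - 0.4*0.5*0.6 = 88%
    assert any_pct == pytest.approx(88.0, abs=2.0)
    assert all_pct == pytest.approx(12.0, abs=2.0)


def test_coexpression_requires_present_gene():
    m = make_count_matrix([[1]], symbols=["A"])
    with pytest.raises(ValueError):
        coexpression_fraction(m, ["Z"], "any")
    with pytest.raises(ValueError):
        coexpression_fraction(m, ["A"], "some")


# -- detection percentile --------------------------------------------------

def test_detection_percentile_midrank():
    dense = np.zeros((5, 60))
    for i, d in enumerate((10, 20, 30, 40, 50)):
        dense[i, :d] = 1
    m = make_count_matrix(dense, symbols=list("ABCDE"))
    r = detection_percentile(m, "D")
    assert r["n_genes_lower"] == 3
    assert r["percentile"] == pytest.approx(75.0)
    assert detection_percentile(m, "E")["percentile"] == pytest.approx(100.0)
    tied = make_count_matrix(np.ones((4, 10)), symbols=list("WXYZ"))
    assert detection_percentile(tied, "X")["percentile"] == pytest.approx(50.0)


# -- standardized summary --------------------------------------------------

def test_standardized_summary_two_groups_and_constant_gene(two_group_norm):
    m, truth, norm = two_group_norm
    g1 = (truth["subpop"] == 1).to_numpy()
    groups = {"grp1": g1, "grp2": ~g1}
    symbols = list(m.genes["symbol"].iloc[:5])
    z = standardized_marker_summary(norm, symbols, groups, gene_symbols=m.genes["symbol"])
    assert np.allclose(z.sum(axis=1), 0.0, atol=1e-10)  # +/- symmetric pairs
    # planted subpop-1 marker: positive z in group 1
    marker = m.genes.loc[m.genes["marker_subpop"] == 1, "symbol"].iloc[0]
    zm = standardized_marker_summary(norm, [marker], groups, gene_symbols=m.genes["symbol"])
    assert zm.loc[marker, "grp1"] > 0 > zm.loc[marker, "grp2"]
    # constant gene gives a zero row
    flat = make_norm(np.ones((1, 40)))
    zc = standardized_marker_summary(flat, ["G0"], {"a": np.arange(20), "b": np.arange(20, 40)})
    assert np.all(zc.to_numpy() == 0.0)
    with pytest.raises(ValueError):
        standardized_marker_summary(norm, symbols, {"only": g1})
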