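"""Synthetic-data generator: rubric, meiosis, gene dropping, moments."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polyblup import (Pedigree, SimConfig, build_A4, fruit_load_score,
                      gene_drop, generate_factorial_pedigree, meiosis_gamete,
                      simulate_dataset, simulate_genotypes,
                      simulate_phenotypes)


# -- fruit-load rubric ------------------------------------------------------

@pytest.mark.parametrize("count,score", [
    (1, 0.5), (3, 0.5), (4, 0.5), (5, 1), (10, 1), (11, 2), (30, 2),
    (31, 3), (60, 3), (100, 4), (150, 5), (250, 6), (350, 7), (450, 8),
    (500, 8), (501, 9), (600, 9), (10_000, 9),
])
def test_fruit_load_rubric(count, score):
    assert fruit_load_score(count) == score


def test_fruit_load_zero_excluded():
    with pytest.raises(ValueError, match="excluded"):
        fruit_load_score(0)
    with pytest.raises(ValueError):
        fruit_load_score(-3)


@given(st.integers(1, 2000), st.integers(1, 2000))
def test_fruit_load_monotone(a, b):
    if a <= b:
        assert fruit_load_score(a) <= fruit_load_score(b)


# -- meiosis ----------------------------------------------------------------

def test_meiosis_no_double_reduction_uniform_pairs(rng):
    counts = {}
    for _ in range(60_000):
        g = meiosis_gamete((0, 1, 2, 3), 0.0, rng)
        assert g[0] != g[1]
        counts[frozenset(g)] = counts.get(frozenset(g), 0) + 1
    freqs = np.array(list(counts.values())) / 60_000
    se = np.sqrt((1 / 6) * (5 / 6) / 60_000)
    assert len(counts) == 6
    assert np.all(np.abs(freqs - 1 / 6) < 3 * se + 1e-9)


def test_meiosis_full_double_reduction(rng):
    for _ in range(200):
        g = meiosis_gamete((0, 1, 2, 3), 1.0, rng)
        assert g[0] == g[1]


def test_meiosis_dosage_law_from_duplex(rng):
    """An AABB (dosage 2) parent without double reduction transmits B-dosage
    (0,1,2) with probabilities (1/6, 4/6, 1/6)."""
    draws = np.array([sum(meiosis_gamete((0, 0, 1, 1), 0.0, rng))
                      for _ in range(60_000)])
    freq = np.bincount(draws, minlength=3) / 60_000
    expected = np.array([1 / 6, 4 / 6, 1 / 6])
    se = np.sqrt(expected * (1 - expected) / 60_000)
    assert np.all(np.abs(freq - expected) < 3 * se + 1e-9)


# -- gene dropping ----------------------------------------------------------

def test_gene_drop_founders_exact(rng):
    ped = Pedigree([(f"f{i}", None, None, "U") for i in range(4)])
    A, se = gene_drop(ped, 0.3, 500, rng)
    assert np.array_equal(A, np.eye(4))
    assert np.array_equal(se, np.zeros((4, 4)))


def test_gene_drop_parent_offspring(rng, trio_pedigree):
    A, se = gene_drop(trio_pedigree, 0.0, 200_000, rng)
    i, k = trio_pedigree.index_of("F1"), trio_pedigree.index_of("P1")
    assert abs(A[i, k] - 0.5) <= 3 * se[i, k]


def test_gene_drop_diagonal_monotone_in_w(rng, fullsib_pedigree):
    k = fullsib_pedigree.index_of("K")
    diags = [gene_drop(fullsib_pedigree, w, 150_000,
                       np.random.default_rng(5))[0][k, k]
             for w in (0.0, 0.1, 0.3)]
    assert diags[0] < diags[1] < diags[2]


# -- pedigree generation ----------------------------------------------------

def test_factorial_design_structure(rng):
    cfg = SimConfig()
    ped, info = generate_factorial_pedigree(cfg, rng)
    assert len(info["parent_ids"]) == 31
    assert len(info["ancestor_ids"]) == 11
    crosses = info["crosses"]
    assert len(crosses) == 50
    assert crosses["n_progeny"].between(2, 80).all()
    assert len(info["progeny_ids"]) == crosses["n_progeny"].sum()
    # every progeny of a cross shares that cross's parents
    pid = info["progeny_ids"][0]
    row = crosses.iloc[0]
    assert ped.parents(pid) == (row["sire"], row["dam"])


def test_single_cross_shares_parents(rng):
    cfg = SimConfig(n_females_block1=1, n_males_block1=1,
                    n_females_block2=1, n_males_block2=1, n_crosses=1,
                    progeny_mean=10, progeny_min=10, progeny_max=10,
                    n_ancestors=0)
    ped, info = generate_factorial_pedigree(cfg, rng)
    parents = {ped.parents(p) for p in info["progeny_ids"]}
    assert len(parents) == 1
    assert len(info["progeny_ids"]) == 10


def test_infeasible_design():
    with pytest.raises(ValueError):
        SimConfig(n_crosses=0)


# -- genotype simulation ----------------------------------------------------

def test_fixation(rng, trio_pedigree):
    cfg = SimConfig(n_markers=5, founder_freq_low=1.0, founder_freq_high=1.0)
    d = simulate_genotypes(trio_pedigree, cfg, rng)
    assert np.all(d.dosage == 4)


def test_founder_dosage_variance(rng):
    ped = Pedigree([(f"f{i}", None, None, "U") for i in range(400)])
    cfg = SimConfig(n_markers=200, founder_freq_low=0.5,
                    founder_freq_high=0.5)
    d = simulate_genotypes(ped, cfg, rng)
    # binomial(4, 1/2) variance = 1
    assert d.dosage.var(axis=0).mean() == pytest.approx(1.0, abs=0.05)


def test_offspring_mean_dosage_equals_midparent(rng):
    recs = [("F", None, None, "F"), ("M", None, None, "M")]
    recs += [(f"k{i}", "F", "M", "U") for i in range(10_000)]
    cfg = SimConfig(n_markers=3, w=0.1)
    d = simulate_genotypes(Pedigree(recs), cfg, rng)
    mid = (d.dosage[0] + d.dosage[1]) / 2.0
    kid_mean = d.dosage[2:].mean(axis=0)
    # transmission is mean-preserving; SE of the mean ~ sqrt(2)/100
    assert np.all(np.abs(kid_mean - mid) < 0.06)


# -- phenotype simulation ---------------------------------------------------

def test_males_receive_no_records(rng):
    ds = simulate_dataset(SimConfig(n_crosses=4, progeny_mean=10,
                                    progeny_min=4, progeny_max=20,
                                    n_ancestors=0, n_markers=10), seed=2)
    sexes = {ds.pedigree.sex(i) for i in ds.phenotypes.data["id"].unique()}
    assert sexes == {"F"}
    # parents are never phenotyped either
    assert not set(ds.info["parent_ids"]) & set(ds.phenotyped_females)


def test_no_genetic_variance_family_structure(rng):
    """With sigma_a^2 = 0 the between-family variance of female means is only
    the sampling noise sigma_e^2 / n-bar."""
    cfg = SimConfig(n_crosses=40, progeny_mean=40, progeny_min=30,
                    progeny_max=50, sigma_a2=0.0, sigma_e2=1.0,
                    n_ancestors=0, year_effects=(0.0,))
    ds = simulate_dataset(cfg, seed=4)
    df = ds.phenotypes.data.merge(
        ds.pedigree.to_frame()[["id", "sire", "dam"]], on="id")
    fam = df.groupby(["sire", "dam"])["value"]
    between = fam.mean().var(ddof=1)
    nbar = fam.size().mean()
    assert between == pytest.approx(1.0 / nbar, rel=0.6)


def test_fullsib_intraclass_correlation(rng):
    """Pedigree-mode additive values give full sibs covariance 0.5 sigma_a^2
    at w = 0, so the intraclass correlation of single-record phenotypes is
    about h2 / 2."""
    cfg = SimConfig(n_crosses=50, progeny_mean=30, progeny_min=20,
                    progeny_max=40, sigma_a2=1.0, sigma_e2=1.0,
                    w=0.0, n_ancestors=0, year_effects=(0.0,))
    ds = simulate_dataset(cfg, seed=6)
    df = ds.phenotypes.data.merge(
        ds.pedigree.to_frame()[["id", "sire", "dam"]], on="id")
    df["fam"] = df["sire"] + "x" + df["dam"]
    grand = df["value"].mean()
    groups = [g["value"].to_numpy() for _, g in df.groupby("fam")]
    nbar = np.mean([len(g) for g in groups])
    msb = np.sum([len(g) * (g.mean() - grand) ** 2 for g in groups]) / (
        len(groups) - 1)
    msw = np.sum([np.sum((g - g.mean()) ** 2) for g in groups]) / (
        len(df) - len(groups))
    icc = (msb - msw) / (msb + (nbar - 1) * msw)
    assert icc == pytest.approx(0.25, abs=0.08)


def test_rubric_discretisation(rng):
    cfg = SimConfig(n_crosses=4, progeny_mean=10, progeny_min=5,
                    progeny_max=20, n_ancestors=0, mu=50.0, sigma_a2=100.0,
                    sigma_e2=100.0, fruit_load_rubric=True)
    ds = simulate_dataset(cfg, seed=8)
    vals = set(ds.phenotypes.data["value"])
    assert vals <= {0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0}


def test_marker_mode_variance_scaling(rng):
    cfg = SimConfig(n_crosses=6, progeny_mean=15, progeny_min=10,
                    progeny_max=20, n_ancestors=0, n_markers=300,
                    sigma_a2=2.0)
    ds = simulate_dataset(cfg, seed=10, genetic_mode="marker")
    a = ds.truth["a"].to_numpy()
    assert a.var() == pytest.approx(2.0, rel=0.05)
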