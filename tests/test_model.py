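"""Animal-model LMM: assembly, REML, MME/BLUP, accuracy."""

import numpy as np
import pandas as pd
import pytest

from polyblup import (BreedingValueModel, ModelSpec, Pedigree,
                      PhenotypeTable, RelationshipMatrix,
                      VarianceComponents, assemble_model, build_A2,
                      build_A4, heritability, reml_fit, solve_mme)
from polyblup.model import _SpectralREML


def _phen(rows):
    return PhenotypeTable(pd.DataFrame(rows,
                                       columns=["id", "year", "trait",
                                                "value"]))


def _randK(rng, q):
    M = rng.standard_normal((q, q + 3))
    return RelationshipMatrix([f"i{k}" for k in range(q)],
                              M @ M.T / (q + 3) + 0.5 * np.eye(q))


def _random_spec(rng, q=None, nrec=None):
    q = q or int(rng.integers(4, 15))
    nrec = nrec or int(rng.integers(q, 2 * q + 1))
    K = _randK(rng, q)
    X = np.column_stack([np.ones(nrec), rng.standard_normal(nrec)])
    Z = np.zeros((nrec, q))
    Z[np.arange(nrec), rng.integers(0, q, nrec)] = 1.0
    y = Z @ rng.standard_normal(q) + rng.standard_normal(nrec)
    return ModelSpec(y, X, Z, K, list(range(nrec)), ["b0", "b1"])


# -- assembly ---------------------------------------------------------------

def test_assemble_dimensions():
    K = RelationshipMatrix(["a", "b"], np.eye(2))
    phen = _phen([("a", 1, "t", 1.0), ("a", 2, "t", 2.0), ("b", 1, "t", 0.5)])
    spec = assemble_model(phen, "t", K)
    assert spec.X.shape == (3, 2)
    assert spec.Z.shape == (3, 2)
    assert spec.x_names == ["intercept", "year[2]"]
    # repeated yearly records map to one individual effect
    assert spec.Z[0].tolist() == spec.Z[1].tolist()


def test_unphenotyped_individual_gets_blup(trio_pedigree):
    K = build_A2(trio_pedigree)
    phen = _phen([("P1", 1, "t", 2.0), ("P1", 2, "t", 3.0),
                  ("F1", 1, "t", 1.0), ("F1", 2, "t", 1.5)])
    res = BreedingValueModel.from_tables(phen, "t", K).fit()
    assert "M1" in res.blups.index
    assert np.isfinite(res.blups.loc["M1"])


def test_single_year_reduces_to_intercept():
    K = RelationshipMatrix(["a", "b", "c"], np.eye(3))
    phen = _phen([("a", 1, "t", 1.0), ("b", 1, "t", 2.0),
                  ("c", 1, "t", 3.0)])
    spec = assemble_model(phen, "t", K)
    assert spec.X.shape[1] == 1


# -- REML -------------------------------------------------------------------

def test_reml_loglik_matches_dense_oracle(rng):
    """Spectral restricted likelihood equals the direct dense formula."""
    spec = _random_spec(rng, q=8, nrec=14)
    work = _SpectralREML(spec)
    for sa2, se2 in [(0.5, 1.0), (2.0, 0.3)]:
        V = sa2 * spec.Z @ spec.K.values @ spec.Z.T + se2 * np.eye(spec.n)
        Vi = np.linalg.inv(V)
        XVX = spec.X.T @ Vi @ spec.X
        b = np.linalg.solve(XVX, spec.X.T @ Vi @ spec.y)
        r = spec.y - spec.X @ b
        ll = -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1]
                     + r @ Vi @ r)
        assert work.loglik(sa2, se2) == pytest.approx(ll, abs=1e-8)


def test_reml_estimates_invariant_to_fixed_parameterization(rng):
    """Treatment vs sum coding of year spans the same column space and must
    give identical variance components."""
    spec = _random_spec(rng, q=10, nrec=20)
    vc1 = reml_fit(spec)
    C = np.array([[1.0, 0.5], [0.0, -0.5]])   # invertible recoding
    spec2 = ModelSpec(spec.y, spec.X @ C, spec.Z, spec.K, spec.record_ids,
                      ["c0", "c1"])
    vc2 = reml_fit(spec2)
    assert vc1.sigma_a2 == pytest.approx(vc2.sigma_a2, rel=1e-6, abs=1e-10)
    assert vc1.sigma_e2 == pytest.approx(vc2.sigma_e2, rel=1e-6, abs=1e-10)


def test_reml_pure_noise_hits_boundary():
    """With no genetic signal sigma_a^2 collapses towards the 0 boundary in
    at least 90% of replicate factorial studies."""
    from polyblup.simulate import SimConfig, simulate_dataset
    from polyblup import build_A4

    hits = 0
    for rep in range(10):
        cfg = SimConfig(sigma_a2=0.0, sigma_e2=1.0)
        ds = simulate_dataset(cfg, seed=800 + rep)
        K = build_A4(ds.pedigree, cfg.w).subset(ds.phenotyped_females)
        vc = reml_fit(assemble_model(ds.phenotypes, "trait", K))
        if heritability(vc) <= 0.05:
            hits += 1
    assert hits >= 9


def test_reml_flags_nonidentifiable_design(rng):
    """K = I with one record each: only sigma_a^2 + sigma_e^2 is estimable;
    the AI matrix must be flagged near-singular."""
    n = 30
    K = RelationshipMatrix([f"i{k}" for k in range(n)], np.eye(n))
    spec = ModelSpec(rng.standard_normal(n), np.ones((n, 1)), np.eye(n), K,
                     list(range(n)), ["mu"])
    vc = reml_fit(spec)
    assert not vc.identifiable


# -- MME --------------------------------------------------------------------

def test_mme_equals_gls_oracle(rng):
    """BLUE/BLUP from the mixed model equations coincide with the GLS form
    sigma_a^2 K Z' V^-1 (y - X b) on random small instances."""
    worst = 0.0
    for _ in range(20):
        spec = _random_spec(rng)
        vc = VarianceComponents(float(rng.uniform(0.2, 2.0)),
                                float(rng.uniform(0.2, 2.0)), True, 0, 0.0)
        res = solve_mme(spec, vc)
        V = (vc.sigma_a2 * spec.Z @ spec.K.values @ spec.Z.T
             + vc.sigma_e2 * np.eye(spec.n))
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(spec.X.T @ Vi @ spec.X, spec.X.T @ Vi @ spec.y)
        a = vc.sigma_a2 * spec.K.values @ spec.Z.T @ Vi @ (spec.y - spec.X @ b)
        worst = max(worst,
                    float(np.abs(res.blups.to_numpy() - a).max()),
                    float(np.abs(res.fixed_effects.to_numpy() - b).max()))
    assert worst < 1e-8


def test_total_shrinkage_limit(rng):
    spec = _random_spec(rng)
    vc = VarianceComponents(0.0, 1.0, True, 0, 0.0)
    res = solve_mme(spec, vc)
    assert np.allclose(res.blups.to_numpy(), 0.0)
    assert np.allclose(res.accuracy().to_numpy(), 0.0)


def test_permutation_invariance(rng):
    spec = _random_spec(rng, q=8, nrec=16)
    vc = VarianceComponents(1.0, 1.0, True, 0, 0.0)
    res = solve_mme(spec, vc)
    perm = rng.permutation(8)
    Kp = RelationshipMatrix([spec.K.ids[i] for i in perm],
                            spec.K.values[np.ix_(perm, perm)])
    spec_p = ModelSpec(spec.y, spec.X, spec.Z[:, perm], Kp, spec.record_ids,
                       spec.x_names)
    res_p = solve_mme(spec_p, vc)
    pd.testing.assert_series_equal(res.blups.sort_index(),
                                   res_p.blups.sort_index(), atol=1e-10)


# -- accuracy / heritability ------------------------------------------------

def _toy_results(kdiag, dia, sa2=1.0, se2=1.0):
    q = len(kdiag)
    K = RelationshipMatrix([f"i{k}" for k in range(q)], np.diag(kdiag))
    spec = ModelSpec(np.zeros(2), np.ones((2, 1)), np.zeros((2, q)), K,
                     [0, 1], ["mu"])
    vc = VarianceComponents(sa2, se2, True, 0, 0.0)
    from polyblup.model import BreedingValueResults
    return BreedingValueResults(spec, vc, np.zeros(1), np.zeros(q),
                                np.asarray(dia))


def test_accuracy_formula_limits():
    # PEV = 0 -> accuracy 1; PEV = sigma_a^2 K_ii -> accuracy 0
    res = _toy_results([1.0, 1.0], [0.0, 1.0], sa2=1.0, se2=1.0)
    acc = res.accuracy().to_numpy()
    assert acc[0] == pytest.approx(1.0)
    assert acc[1] == pytest.approx(0.0)


def test_accuracy_kii_convention():
    # A4w diagonal 1.3 means F = 0.1 -> one-plus-f denominator uses 1.1
    q = 1
    K = RelationshipMatrix(["x"], np.array([[1.3]]), method="A4w", ploidy=4)
    spec = ModelSpec(np.zeros(2), np.ones((2, 1)), np.zeros((2, 1)), K,
                     [0, 1], ["mu"])
    vc = VarianceComponents(1.0, 1.0, True, 0, 0.0)
    from polyblup.model import BreedingValueResults
    res = BreedingValueResults(spec, vc, np.zeros(1), np.zeros(q),
                               np.array([0.65]))
    assert res.accuracy("matrix").iloc[0] == pytest.approx(
        np.sqrt(1 - 0.65 / 1.3))
    assert res.accuracy("one-plus-f").iloc[0] == pytest.approx(
        np.sqrt(1 - 0.65 / 1.1))


def test_unphenotyped_fullsibs_share_accuracy():
    """Two unphenotyped full sibs are exchangeable under a pedigree K."""
    ped = Pedigree([
        ("F1", None, None, "F"), ("M1", None, None, "M"),
        ("F2", None, None, "F"), ("M2", None, None, "M"),
        ("a1", "F1", "M1", "F"), ("a2", "F1", "M1", "F"),
        ("u1", "F1", "M1", "M"), ("u2", "F1", "M1", "M"),
        ("b1", "F2", "M2", "F"), ("b2", "F2", "M2", "F"),
    ])
    for K in (build_A2(ped), build_A4(ped, 0.1)):
        phen = _phen([(i, y, "t", v) for i, y, v in
                      [("a1", 1, 2.0), ("a1", 2, 2.5), ("a2", 1, 1.0),
                       ("a2", 2, 1.4), ("b1", 1, 0.3), ("b1", 2, 0.1),
                       ("b2", 1, -1.0), ("b2", 2, -0.6)]])
        res = BreedingValueModel.from_tables(phen, "t", K).fit(
            vc=VarianceComponents(0.8, 1.2, True, 0, 0.0))
        acc = res.accuracy()
        assert acc.loc["u1"] == pytest.approx(acc.loc["u2"], abs=1e-10)
        # own records add information
        assert acc.loc["a1"] >= acc.loc["u1"] - 1e-10


@pytest.mark.parametrize("sa2,se2,h2", [(1, 1, 0.5), (0, 1, 0.0),
                                        (2, 1e-12, 1.0)])
def test_heritability_formula(sa2, se2, h2):
    vc = VarianceComponents(sa2, se2, True, 0, 0.0)
    assert heritability(vc) == pytest.approx(h2, abs=1e-9)
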