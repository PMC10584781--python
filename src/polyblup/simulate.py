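"""Synthetic dioecious factorial populations with tetrasomic inheritance.

This module generates data with the structure the analysis assumes — and
nothing more: two incomplete factorial crossing blocks (many females by few
males, and the mirror image), tetrasomic meiosis with whole-gamete double
reduction at rate ``w``, unlinked biallelic markers, and sex-limited
multi-year phenotypes following the same linear mixed model the estimator
fits. It also houses the gene-dropping Monte-Carlo estimator of
identity-by-descent, the independent oracle against which the closed-form
relationship-matrix recursions are validated.

Defaults mirror the motivating kiwiberry breeding design: ~50 crosses from
31 parents (a 14-female x 2-male block plus a 13-male x 2-female block),
36 progeny per cross on average within a 2-80 range, an even sex ratio, and
phenotype records on female progeny only over 2 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._genedrop import _drop_di, _drop_tetra
from .amatrix import build_A4
from .dosage import DosageMatrix
from .pedigree import Pedigree
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig", "SimDataset", "fruit_load_score",
    "generate_factorial_pedigree", "meiosis_gamete", "gene_drop",
    "simulate_genotypes", "simulate_phenotypes", "simulate_dataset",
]


# ---------------------------------------------------------------------------
# fruit-load scoring rubric
# ---------------------------------------------------------------------------

#: (upper fruit count, score); counts above the last bound score 9
_FRUIT_BINS = [(4, 0.5), (10, 1), (30, 2), (60, 3), (100, 4),
               (200, 5), (300, 6), (400, 7), (500, 8)]


def fruit_load_score(count: int) -> float:
    """Ordinal fruit-load score of a vine bearing ``count`` fruits.

    Step function: up to 4 fruits scores 0.5; up to 10, 30, 60, 100, 200,
    300, 400 and 500 fruits score 1..8; more than 500 scores 9. A count of
    zero (no fruit) is excluded from analysis and raises ValueError.
    """
    if count != int(count) or count < 0:
        raise ValueError(f"fruit count must be a non-negative integer, "
                         f"got {count!r}")
    if count == 0:
        raise ValueError("fruit count 0 (no fruit) is an excluded record")
    for bound, score in _FRUIT_BINS:
        if count <= bound:
            return float(score)
    return 9.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    The crossing-design defaults reproduce the reference breeding design;
    ``w`` is the double-reduction rate of tetrasomic meiosis.
    """

    # factorial blocks: females x males and males x females
    n_females_block1: int = 14
    n_males_block1: int = 2
    n_males_block2: int = 13
    n_females_block2: int = 2
    n_crosses: int = 50
    progeny_mean: float = 36.0
    progeny_min: int = 2
    progeny_max: int = 80
    progeny_dispersion: float = 4.0     # negative-binomial size parameter
    sex_ratio: float = 0.5              # P(female)
    n_ancestors: int = 11               # distant founders above the parents
    # inheritance
    w: float = 0.1
    n_markers: int = 5000
    founder_freq_low: float = 0.1
    founder_freq_high: float = 0.9
    # trait model
    trait: str = "trait"
    mu: float = 10.0
    year_effects: tuple = (0.0, 0.5)
    sigma_a2: float = 1.0
    sigma_e2: float = 1.0
    missing_rate: float = 0.0           # P(drop a record), emulates gaps
    fruit_load_rubric: bool = False     # discretise through the scoring bins
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")
        if self.n_crosses < 1:
            raise ValueError("need at least one cross")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex ratio must lie in (0, 1)")

    @property
    def h2(self) -> float:
        sp2 = self.sigma_a2 + self.sigma_e2
        return 0.0 if sp2 == 0 else self.sigma_a2 / sp2

    @property
    def n_years(self) -> int:
        return len(self.year_effects)


# ---------------------------------------------------------------------------
# pedigree generation
# ---------------------------------------------------------------------------

def _truncated_negbin(rng, mean, disp, lo, hi):
    p = disp / (disp + mean)
    for _ in range(1000):
        x = int(rng.negative_binomial(disp, p))
        if lo <= x <= hi:
            return x
    return int(np.clip(round(mean), lo, hi))


def generate_factorial_pedigree(cfg: SimConfig, rng) -> tuple:
    """Two incomplete factorial blocks with the configured cross list.

    Returns (Pedigree, info) where info holds ``progeny_ids``,
    ``parent_ids``, ``ancestor_ids`` and the cross table.
    """
    rng = np.random.default_rng(rng)
    recs = []
    anc_f, anc_m = [], []
    for i in range(cfg.n_ancestors):
        sex = "F" if i % 2 == 0 else "M"
        aid = f"A{i + 1:02d}"
        (anc_f if sex == "F" else anc_m).append(aid)
        recs.append((aid, None, None, sex))

    def parent_of(sex):
        # parents descend from the distant-ancestor pool when available
        if anc_f and anc_m:
            return rng.choice(anc_m), rng.choice(anc_f)
        return None, None

    fem1 = [f"PF{i + 1:02d}" for i in range(cfg.n_females_block1)]
    mal1 = [f"PM{i + 1:02d}" for i in range(cfg.n_males_block1)]
    mal2 = [f"PM{i + 1 + cfg.n_males_block1:02d}"
            for i in range(cfg.n_males_block2)]
    fem2 = [f"PF{i + 1 + cfg.n_females_block1:02d}"
            for i in range(cfg.n_females_block2)]
    for pid in fem1 + fem2:
        s, d = parent_of("F")
        recs.append((pid, s, d, "F"))
    for pid in mal1 + mal2:
        s, d = parent_of("M")
        recs.append((pid, s, d, "M"))

    grid = [(f, m) for f in fem1 for m in mal1]
    grid += [(f, m) for f in fem2 for m in mal2]
    if cfg.n_crosses > len(grid):
        raise ValueError(
            f"{cfg.n_crosses} crosses requested but the factorial grids "
            f"only offer {len(grid)} parent combinations")
    pick = rng.choice(len(grid), size=cfg.n_crosses, replace=False)
    crosses, progeny = [], []
    for c, gi in enumerate(sorted(pick), start=1):
        dam, sire = grid[gi]
        n_prog = _truncated_negbin(rng, cfg.progeny_mean,
                                   cfg.progeny_dispersion,
                                   cfg.progeny_min, cfg.progeny_max)
        if n_prog == 0:
            logger.info("cross %d (%s x %s) drew zero progeny, omitted",
                        c, sire, dam)
            continue
        crosses.append({"cross": c, "sire": sire, "dam": dam,
                        "n_progeny": n_prog})
        for k in range(1, n_prog + 1):
            pid = f"C{c:02d}_{k:03d}"
            sex = "F" if rng.random() < cfg.sex_ratio else "M"
            recs.append((pid, sire, dam, sex))
            progeny.append(pid)
    if not crosses:
        raise ValueError("design produced no crosses with progeny")
    info = {
        "progeny_ids": progeny,
        "parent_ids": fem1 + fem2 + mal1 + mal2,
        "ancestor_ids": anc_f + anc_m,
        "crosses": pd.DataFrame(crosses),
    }
    return Pedigree(recs), info


# ---------------------------------------------------------------------------
# meiosis and gene dropping
# ---------------------------------------------------------------------------

def meiosis_gamete(parent_alleles, w: float, rng) -> tuple:
    """One tetrasomic gamete (2 allele copies) from 4 parental copies.

    With probability ``w`` a double-reduction event duplicates a single
    uniformly chosen copy; otherwise two distinct copies are drawn without
    replacement.
    """
    rng = np.random.default_rng(rng)
    alleles = list(parent_alleles)
    if len(alleles) != 4:
        raise ValueError("tetrasomic meiosis needs 4 allele copies")
    if rng.random() < w:
        a = alleles[rng.integers(4)]
        return (a, a)
    i, j = rng.choice(4, size=2, replace=False)
    return (alleles[i], alleles[j])


def gene_drop(ped: Pedigree, w: float, n_replicates: int, rng,
              ploidy: int = 4) -> tuple:
    """Monte-Carlo ploidy-scaled coancestry (ploidy x theta-hat) with MC SEs.

    Unique founder labels are dropped through the ordered pedigree
    ``n_replicates`` times; theta-hat_ij is the fraction of ordered allele
    pairs (one from i, one from j, with replacement on the diagonal) sharing
    a label. Returns (A_hat, se) as ndarrays in ``ped.ids`` order; founder
    entries are exact (se 0).
    """
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))
    par = np.asarray(ped.parent_indices(), dtype=np.int64).reshape(ped.n, 2)
    if ploidy == 4:
        s_m, s_m2 = _drop_tetra(par, float(w), int(n_replicates), seed)
        scale = 4.0
    elif ploidy == 2:
        s_m, s_m2 = _drop_di(par, int(n_replicates), seed)
        scale = 2.0
    else:
        raise ValueError("ploidy must be 2 or 4")
    R = n_replicates
    mean_m = s_m / R
    var_m = np.maximum(s_m2 / R - mean_m**2, 0.0)
    A = mean_m / scale
    se = np.sqrt(var_m / R) / scale
    A = np.triu(A) + np.triu(A, 1).T
    se = np.triu(se) + np.triu(se, 1).T
    return A, se


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _vec_gamete(P, w, rng):
    """Vectorised tetrasomic gametes across L unlinked loci.

    P is the parent's (L, 4) allele array; returns (L, 2).
    """
    L = P.shape[0]
    rows = np.arange(L)
    dr = rng.random(L) < w
    c1 = rng.integers(0, 4, L)
    c2 = rng.integers(0, 3, L)
    c2 = c2 + (c2 >= c1)
    a1 = P[rows, c1]
    a2 = np.where(dr, a1, P[rows, c2])
    return np.stack([a1, a2], axis=1)


def simulate_genotypes(ped: Pedigree, cfg: SimConfig, rng) -> DosageMatrix:
    """Tetraploid dosages at ``cfg.n_markers`` unlinked biallelic loci.

    Founder allele copies are Bernoulli(p_j) with p_j drawn from
    Uniform(founder_freq_low, founder_freq_high); descendants receive one
    gamete from each parent per locus via tetrasomic meiosis with double
    reduction ``cfg.w``. A missing parent contributes gametes from a fresh
    founder drawn from the same frequency law.
    """
    rng = np.random.default_rng(rng)
    L = cfg.n_markers
    p = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, L)
    n = ped.n
    par = ped.parent_indices()
    alleles = np.empty((n, L, 4), dtype=np.int8)
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            alleles[i] = rng.random((L, 4)) < p[:, None]
            continue
        for g, parent in enumerate((s, d)):
            if parent < 0:
                phantom = (rng.random((L, 4)) < p[:, None]).astype(np.int8)
                gam = _vec_gamete(phantom, cfg.w, rng)
            else:
                gam = _vec_gamete(alleles[parent], cfg.w, rng)
            alleles[i, :, 2 * g:2 * g + 2] = gam
    dosage = alleles.sum(axis=2, dtype=np.int64)
    markers = [f"M{j + 1:05d}" for j in range(L)]
    return DosageMatrix(ped.ids, markers, dosage, ploidy=4)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

def simulate_phenotypes(ped: Pedigree, cfg: SimConfig, rng,
                        genetic_mode: str = "pedigree",
                        genotypes: Optional[DosageMatrix] = None,
                        phenotyped_ids: Optional[list] = None,
                        A: Optional[np.ndarray] = None) -> tuple:
    """Sex-limited multi-year phenotypes from the generative animal model.

    Breeding values a are drawn from N(0, A(w) sigma_a^2) in ``pedigree``
    mode, or constructed as a linear combination of centred marker dosages
    rescaled to additive variance sigma_a^2 in ``marker`` mode (so markers
    fully determine the additive value). Records y_it = mu + year_t + a_i +
    e_it are emitted for phenotyped females only (default: females with both
    parents known).

    Returns (PhenotypeTable, truth) with truth carrying the true breeding
    values and variance components.
    """
    rng = np.random.default_rng(rng)
    n = ped.n
    if genetic_mode == "pedigree":
        if cfg.sigma_a2 > 0:
            Amat = build_A4(ped, cfg.w).values if A is None else np.asarray(A)
            try:
                Lc = np.linalg.cholesky(Amat + 1e-10 * np.eye(n))
            except np.linalg.LinAlgError as e:
                raise ValueError(
                    "relationship matrix for phenotype simulation is not "
                    "positive semi-definite") from e
            a = np.sqrt(cfg.sigma_a2) * (Lc @ rng.standard_normal(n))
        else:
            a = np.zeros(n)
    elif genetic_mode == "marker":
        if genotypes is None:
            raise ValueError("marker mode requires genotypes")
        W = genotypes.dosage - genotypes.dosage.mean(axis=0)[None, :]
        beta = rng.standard_normal(genotypes.m)
        a0 = W @ beta
        sd0 = a0.std()
        a = (a0 * np.sqrt(cfg.sigma_a2) / sd0 if sd0 > 0
             else np.zeros(len(a0)))
        order = [genotypes.ids.index(i) for i in ped.ids]
        a = a[order]
    else:
        raise ValueError(f"unknown genetic mode {genetic_mode!r}")

    if phenotyped_ids is None:
        phenotyped_ids = [r[0] for r in ped.records
                          if r[3] == "F" and r[1] is not None
                          and r[2] is not None]
    rows = []
    se = np.sqrt(cfg.sigma_e2)
    for iid in phenotyped_ids:
        ai = a[ped.index_of(iid)]
        for t, yeff in enumerate(cfg.year_effects, start=1):
            if cfg.missing_rate and rng.random() < cfg.missing_rate:
                continue
            val = cfg.mu + yeff + ai + se * rng.standard_normal()
            if cfg.fruit_load_rubric:
                count = int(max(round(val), 0))
                if count == 0:
                    continue
                val = fruit_load_score(count)
            rows.append((iid, t, cfg.trait, val))
    tab = PhenotypeTable(pd.DataFrame(rows,
                                      columns=["id", "year", "trait",
                                               "value"]))
    truth = {
        "a": pd.Series(a, index=ped.ids),
        "sigma_a2": cfg.sigma_a2, "sigma_e2": cfg.sigma_e2,
        "h2": cfg.h2, "w": cfg.w, "mode": genetic_mode,
    }
    return tab, truth


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    """A complete synthetic study: pedigree, genotypes, phenotypes, truth."""

    pedigree: Pedigree
    genotypes: Optional[DosageMatrix]
    phenotypes: PhenotypeTable
    truth: dict
    info: dict = field(default_factory=dict)

    @property
    def phenotyped_females(self) -> list:
        return list(dict.fromkeys(self.phenotypes.data["id"]))


def simulate_dataset(cfg: SimConfig, seed: Optional[int] = None,
                     genetic_mode: str = "pedigree",
                     with_genotypes: Optional[bool] = None) -> SimDataset:
    """Generate a full study dataset under ``cfg``.

    Only female cross progeny are phenotyped (parents and ancestors never
    are), mirroring a dioecious trial. Genotypes are simulated when
    ``with_genotypes`` is true or marker-mode phenotypes require them.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ped, info = generate_factorial_pedigree(cfg, rng)
    if with_genotypes is None:
        with_genotypes = genetic_mode == "marker"
    geno = simulate_genotypes(ped, cfg, rng) if with_genotypes else None
    fem_progeny = [i for i in info["progeny_ids"] if ped.sex(i) == "F"]
    phen, truth = simulate_phenotypes(
        ped, cfg, rng, genetic_mode=genetic_mode, genotypes=geno,
        phenotyped_ids=fem_progeny)
    return SimDataset(ped, geno, phen, truth, info)
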