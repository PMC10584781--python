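"""Repeated k-fold cross-validation of breeding-value prediction.

Only phenotyped females enter the folds (parents and males carry no records
and can never be validated). In each fold the validation group's records are
masked, variance components are re-estimated by REML on the training records
alone, BLUPs are predicted for everyone, and the fold statistics compare the
validation individuals' mean observed phenotype across years with their
predicted breeding values:

* predictive ability PA — Pearson correlation(observed mean, prediction);
* bias — least-squares slope of observed means on predictions (1 = neither
  inflated nor deflated);
* MSE — mean squared difference;
* expected genetic gain EGG = 1/2 * PA * sigma_a * i / L (i = L = 1 by
  default, so per-cycle gain on the trait scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import assemble_model, reml_fit, solve_mme
from .phenotypes import PhenotypeTable
from .relationship import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan", "CVReport", "make_folds", "run_cv", "predictive_ability",
    "bias", "mse", "expected_genetic_gain", "summarize_trait",
]


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

def predictive_ability(obs_mean, pred) -> float:
    """Pearson correlation of observed phenotype means with predictions.

    Returns NaN (excluded from aggregates) when fewer than 3 pairs or a
    constant vector make the correlation undefined.
    """
    obs = np.asarray(obs_mean, dtype=float)
    prd = np.asarray(pred, dtype=float)
    if obs.size < 3 or np.ptp(obs) == 0 or np.ptp(prd) == 0:
        return float("nan")
    return float(np.corrcoef(obs, prd)[0, 1])


def bias(obs_mean, pred) -> float:
    """Regression slope of observed means on predictions.

    Slope 1 marks unbiased dispersion; > 1 means predictions are
    under-dispersed (over-shrunk), < 1 over-dispersed.
    """
    obs = np.asarray(obs_mean, dtype=float)
    prd = np.asarray(pred, dtype=float)
    if prd.size < 2 or np.ptp(prd) == 0:
        return float("nan")
    px = prd - prd.mean()
    return float((px @ (obs - obs.mean())) / (px @ px))


def mse(obs_mean, pred) -> float:
    """Mean squared difference between observed means and predictions."""
    obs = np.asarray(obs_mean, dtype=float)
    prd = np.asarray(pred, dtype=float)
    return float(np.mean((obs - prd) ** 2))


def expected_genetic_gain(pa: float, sigma_a: float, i: float = 1.0,
                          L: float = 1.0) -> float:
    """Expected genetic gain per cycle, dG = 1/2 * PA * sigma_a * i / L.

    ``i`` is the selection intensity and ``L`` the breeding-cycle length;
    both default to 1 so models stay comparable.
    """
    if sigma_a < 0:
        raise ValueError("sigma_a must be non-negative")
    return 0.5 * pa * sigma_a * i / L


def summarize_trait(values) -> dict:
    """Order statistics and moment skewness of a trait sample.

    Returns min, q1, median, mean, q3, max and the moment-based skewness
    m3 / m2^(3/2) (same convention as R's "moments" package).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need at least 3 finite values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return {
        "min": float(v.min()), "q1": float(q1), "median": float(med),
        "mean": float(v.mean()), "q3": float(q3), "max": float(v.max()),
        "skewness": float(stats.skew(v, bias=True)), "n": int(v.size),
    }


# ---------------------------------------------------------------------------
# fold planning
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    repeat: int
    fold: int
    validation_ids: list
    training_ids: list
    seed: int


def make_folds(ids, k: int = 10, repeats: int = 10,
               seed: Optional[int] = None) -> list:
    """Random partitions of ``ids`` into ``k`` near-equal folds, ``repeats``
    times. Within a repeat every id appears in exactly one validation set."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of ids ({len(ids)})")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(1, repeats + 1):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        order = np.random.default_rng(sub_seed).permutation(len(ids))
        groups = np.array_split(order, k)
        for f, g in enumerate(groups, start=1):
            val = [ids[i] for i in g]
            val_set = set(val)
            train = [i for i in ids if i not in val_set]
            plans.append(FoldPlan(rep, f, val, train, sub_seed))
    return plans


# ---------------------------------------------------------------------------
# the harness
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    folds: pd.DataFrame          # per (repeat, fold) statistics
    trait: str
    method: str
    n_failed: int = 0
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    _STATS = ["pa", "bias", "mse", "egg", "sigma_a2", "sigma_e2", "h2"]

    def aggregate(self) -> pd.DataFrame:
        """Unweighted mean and sd over all successful (repeat, fold) cells."""
        ok = self.folds
        return pd.DataFrame({"mean": ok[self._STATS].mean(),
                             "sd": ok[self._STATS].std(ddof=1)})

    def to_dict(self) -> dict:
        agg = self.aggregate()
        return {
            "trait": self.trait, "method": self.method, "seed": self.seed,
            "n_folds": int(len(self.folds)), "n_failed": self.n_failed,
            "aggregates": {s: {"mean": float(agg.loc[s, "mean"]),
                               "sd": float(agg.loc[s, "sd"])}
                           for s in self._STATS},
            **self.meta,
        }

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            f"Cross-validation: trait={self.trait} method={self.method} "
            f"({len(self.folds)} folds, {self.n_failed} failed)",
            f"{'statistic':<10s}{'mean':>12s}{'sd':>12s}",
        ]
        for s in self._STATS:
            lines.append(f"{s:<10s}{agg.loc[s, 'mean']:>12.4f}"
                         f"{agg.loc[s, 'sd']:>12.4f}")
        return "\n".join(lines)


def run_cv(phen: PhenotypeTable, trait: str, K: RelationshipMatrix,
           plans: list, blend: Optional[float] = None,
           per_record: bool = False, pooled_per_repeat: bool = False,
           tol: float = 1e-8, max_iter: int = 200,
           selection_intensity: float = 1.0, cycle_length: float = 1.0
           ) -> CVReport:
    """Run the masking cross-validation over prepared fold plans.

    For each fold the validation individuals' records are dropped, REML and
    the MME are re-solved on training records only, and statistics compare
    validation observations (mean over years, or per-record with
    ``per_record=True``) against predicted breeding values. Folds whose REML
    fails to converge are flagged and excluded from aggregates.
    ``pooled_per_repeat`` pools all validation pairs of a repeat before
    computing the statistics instead of averaging per-fold values.
    """
    if blend:
        K = K.blend(blend)
    data = phen.for_trait(trait)
    obs_mean = phen.mean_by_id(trait)
    rows, n_failed = [], 0
    pooled = {}
    for plan in plans:
        train_set = set(plan.training_ids)
        sub = PhenotypeTable(data[data["id"].isin(train_set)])
        spec = assemble_model(sub, trait, K)
        vc = reml_fit(spec, tol=tol, max_iter=max_iter)
        if not vc.converged:
            n_failed += 1
            logger.warning("fold (%d,%d): REML non-convergence, excluded",
                           plan.repeat, plan.fold)
            continue
        res = solve_mme(spec, vc)
        if per_record:
            vrec = data[data["id"].isin(set(plan.validation_ids))]
            obs = vrec["value"].to_numpy()
            prd = res.blups.loc[vrec["id"]].to_numpy()
        else:
            obs = obs_mean.loc[plan.validation_ids].to_numpy()
            prd = res.blups.loc[plan.validation_ids].to_numpy()
        pooled.setdefault(plan.repeat, []).append(
            (obs, prd, vc.sigma_a2, vc.sigma_e2))
        pa = predictive_ability(obs, prd)
        rows.append({
            "repeat": plan.repeat, "fold": plan.fold,
            "n_validation": len(obs), "pa": pa,
            "bias": bias(obs, prd), "mse": mse(obs, prd),
            "egg": expected_genetic_gain(pa, np.sqrt(vc.sigma_a2),
                                         selection_intensity, cycle_length),
            "sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2, "h2": vc.h2,
        })
    if pooled_per_repeat:
        rows = []
        for rep, parts in sorted(pooled.items()):
            obs = np.concatenate([p[0] for p in parts])
            prd = np.concatenate([p[1] for p in parts])
            sa2 = float(np.mean([p[2] for p in parts]))
            se2 = float(np.mean([p[3] for p in parts]))
            pa = predictive_ability(obs, prd)
            rows.append({
                "repeat": rep, "fold": 0, "n_validation": len(obs), "pa": pa,
                "bias": bias(obs, prd), "mse": mse(obs, prd),
                "egg": expected_genetic_gain(pa, np.sqrt(sa2),
                                             selection_intensity,
                                             cycle_length),
                "sigma_a2": sa2, "sigma_e2": se2, "h2": sa2 / (sa2 + se2),
            })
    folds = pd.DataFrame(rows)
    return CVReport(folds=folds, trait=trait, method=K.method,
                    n_failed=n_failed)
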