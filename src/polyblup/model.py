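"""Animal-model LMM for breeding-value prediction.

The model is

    y = X b + Z a + e,    a ~ N(0, K sigma_a^2),    e ~ N(0, I sigma_e^2)

with y the phenotype records of one trait, X an intercept plus
treatment-coded year effects (the overall mean mu is absorbed into the
intercept), Z the record->individual incidence over *all* individuals in the
relationship matrix K (so unphenotyped individuals — males, parents,
ancestors — receive BLUPs), and K any of A2/A4/A4w/G2/G4.

Variance components are estimated by average-information REML with
step-halving and a positivity-preserving multiplicative fallback, run on the
spectral reparameterisation V = sigma_a^2 Q + sigma_e^2 I, Q = Z K Z' =
U diag(d) U': after one symmetric eigendecomposition per dataset every REML
quantity (restricted log-likelihood, scores, AI matrix) costs O(n p) per
iteration.

BLUE/BLUP and their prediction-error variances come from Henderson's mixed
model equations

    [X'X   X'Z       ] [b]   [X'y]
    [Z'X   Z'Z + K^-1 lambda] [a] = [Z'y],   lambda = sigma_e^2 / sigma_a^2,

whose inverse-coefficient-matrix diagonal d_i gives PEV_i = d_i sigma_e^2,
SEP_i = sqrt(PEV_i) and accuracy_i = sqrt(1 - PEV_i / (sigma_a^2 K_ii)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .phenotypes import PhenotypeTable
from .relationship import RelationshipMatrix, inbreeding_from_diagonal

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "VarianceComponents", "BreedingValueModel",
    "BreedingValueResults", "assemble_model", "reml_fit", "solve_mme",
    "accuracy", "heritability",
]


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Design matrices for one trait against one relationship matrix."""

    y: np.ndarray              # (n,) responses
    X: np.ndarray              # (n, p) intercept + year contrasts
    Z: np.ndarray              # (n, q) record -> individual incidence
    K: RelationshipMatrix      # (q, q), ids give the BLUP order
    record_ids: list
    x_names: list
    trait: str = ""

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.K.n


def assemble_model(phen: PhenotypeTable, trait: str,
                   K: RelationshipMatrix) -> ModelSpec:
    """Build y, X (intercept + treatment-coded year) and Z from records.

    Repeated yearly records of an individual map to the same additive
    effect; individuals present in K but never phenotyped get all-zero Z
    columns and still receive BLUPs.
    """
    sub = phen.for_trait(trait)
    unknown = [i for i in sub["id"].unique() if i not in set(K.ids)]
    if unknown:
        raise ValueError(
            f"phenotyped id(s) missing from relationship matrix: "
            f"{unknown[:5]}")
    if len(sub) < 2:
        raise ValueError("need at least 2 records")
    y = sub["value"].to_numpy(dtype=float)
    years = sorted(sub["year"].unique())
    n = len(sub)
    X = np.ones((n, len(years)))
    x_names = ["intercept"]
    for c, yr in enumerate(years[1:], start=1):
        X[:, c] = (sub["year"] == yr).to_numpy(dtype=float)
        x_names.append(f"year[{yr}]")
    if len(years) == 1:
        logger.info("single year level for trait %r: X is intercept only",
                    trait)
    pos = {iid: j for j, iid in enumerate(K.ids)}
    Z = np.zeros((n, K.n))
    Z[np.arange(n), [pos[i] for i in sub["id"]]] = 1.0
    return ModelSpec(y=y, X=X, Z=Z, K=K, record_ids=list(sub["id"]),
                     x_names=x_names, trait=trait)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    converged: bool
    n_iterations: int
    loglik: float
    se: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))
    ai_condition: float = np.nan
    boundary: bool = False

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return heritability(self)

    @property
    def lam(self) -> float:
        """Shrinkage factor lambda = sigma_e^2 / sigma_a^2."""
        return np.inf if self.sigma_a2 <= 0 else self.sigma_e2 / self.sigma_a2

    @property
    def identifiable(self) -> bool:
        return bool(np.isfinite(self.ai_condition)
                    and self.ai_condition < 1e8)


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability h2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)."""
    sp2 = vc.sigma_a2 + vc.sigma_e2
    return 0.0 if sp2 <= 0 else vc.sigma_a2 / sp2


class _SpectralREML:
    """REML working quantities on the eigenbasis of Q = Z K Z'."""

    def __init__(self, spec: ModelSpec):
        Q = spec.Z @ spec.K.values @ spec.Z.T
        d, U = eigh((Q + Q.T) / 2.0)
        self.d = np.clip(d, 0.0, None)
        self.yt = U.T @ spec.y
        self.Xt = U.T @ spec.X
        self.n, self.p = self.Xt.shape

    def _common(self, sa2, se2):
        w = sa2 * self.d + se2
        Xw = self.Xt / w[:, None]
        T = self.Xt.T @ Xw
        Tc = cho_factor(T, lower=True)
        beta = cho_solve(Tc, Xw.T @ self.yt)
        r = self.yt - self.Xt @ beta
        py = r / w
        return w, Xw, Tc, py, r

    def _apply_P(self, v, w, Xw, Tc):
        vw = v / w
        return vw - Xw @ cho_solve(Tc, self.Xt.T @ vw)

    def loglik(self, sa2, se2):
        w, Xw, Tc, py, r = self._common(sa2, se2)
        logdetV = float(np.sum(np.log(w)))
        logdetT = 2.0 * float(np.sum(np.log(np.diag(Tc[0]))))
        return -0.5 * (logdetV + logdetT + float(r @ py))

    def score_ai(self, sa2, se2):
        w, Xw, Tc, py, r = self._common(sa2, se2)
        scores, yPQPy, trPQ, u = [], [], [], []
        for g in (self.d, np.ones(self.n)):
            Mg = Xw.T @ (Xw * g[:, None])
            tr = float(np.sum(g / w) - np.trace(cho_solve(Tc, Mg)))
            ug = g * py
            yq = float(py @ ug)
            scores.append(-0.5 * (tr - yq))
            yPQPy.append(yq)
            trPQ.append(tr)
            u.append(ug)
        AI = np.empty((2, 2))
        Pu = [self._apply_P(ui, w, Xw, Tc) for ui in u]
        for i in range(2):
            for j in range(i, 2):
                AI[i, j] = AI[j, i] = 0.5 * float(u[i] @ Pu[j])
        return (np.asarray(scores), AI, np.asarray(yPQPy), np.asarray(trPQ))


def reml_fit(spec: ModelSpec, tol: float = 1e-8,
             max_iter: int = 200) -> VarianceComponents:
    """Average-information REML for (sigma_a^2, sigma_e^2).

    Non-convergence in ``max_iter`` is flagged (``converged=False``), not
    raised; a fit pinned at the sigma_a^2 = 0 boundary is reported via
    ``boundary=True``. Near-singularity of the AI matrix (non-identifiable
    designs, e.g. K = I with one record per individual) is exposed through
    ``ai_condition`` and the ``identifiable`` property.
    """
    work = _SpectralREML(spec)
    n, p = work.n, work.p
    # start from an even split of the OLS residual variance
    Xls, *_ = np.linalg.lstsq(spec.X, spec.y, rcond=None)
    r0 = spec.y - spec.X @ Xls
    sp2 = max(float(r0 @ r0) / max(n - p, 1), 1e-12)
    sa2, se2 = 0.5 * sp2, 0.5 * sp2
    floor_e = 1e-10 * sp2
    converged = False
    AI = np.full((2, 2), np.nan)
    it = 0
    for it in range(1, max_iter + 1):
        score, AI, yPQPy, trPQ = work.score_ai(sa2, se2)
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = None
        new = None
        if step is not None:
            cand = np.array([sa2, se2]) + step
            for _ in range(30):
                if cand[0] >= 0 and cand[1] >= floor_e:
                    new = cand
                    break
                step = step / 2.0
                cand = np.array([sa2, se2]) + step
        if new is None:
            # positivity-preserving multiplicative fallback step
            ratio = np.sqrt(yPQPy / np.maximum(trPQ, 1e-300))
            new = np.array([max(sa2, 1e-12 * sp2) * ratio[0],
                            max(se2, floor_e) * ratio[1]])
            new[0] = max(new[0], 0.0)
            new[1] = max(new[1], floor_e)
        denom = np.maximum(np.abs([sa2, se2]), 1e-8 * sp2)
        delta = float(np.max(np.abs(new - [sa2, se2]) / denom))
        # at the sigma_a^2 = 0 boundary the relative criterion cannot fire;
        # accept once sigma_a^2 is negligible and sigma_e^2 has stabilised
        at_boundary = (max(sa2, float(new[0])) < 1e-8 * sp2
                       and abs(new[1] - se2) < tol * max(se2, floor_e))
        sa2, se2 = float(new[0]), float(new[1])
        if delta < tol or at_boundary:
            converged = True
            break
    score, AI, _, _ = work.score_ai(sa2, se2)
    with np.errstate(all="ignore"):
        cond = float(np.linalg.cond(AI))
        try:
            se = np.sqrt(np.clip(np.diag(np.linalg.inv(AI)), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(2, np.nan)
    boundary = sa2 <= 1e-6 * sp2
    if boundary:
        logger.info("sigma_a^2 pinned at the zero boundary")
    if cond >= 1e8:
        logger.warning("AI matrix near-singular (cond=%.2g): variance "
                       "components not separately identifiable", cond)
    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)
    return VarianceComponents(sigma_a2=sa2, sigma_e2=se2, converged=converged,
                              n_iterations=it,
                              loglik=work.loglik(sa2, se2), se=se,
                              ai_condition=cond, boundary=boundary)


# ---------------------------------------------------------------------------
# MME / BLUP / accuracy
# ---------------------------------------------------------------------------

def _chol_jitter(M, start=1e-10, stop=1e-6):
    try:
        return cho_factor(M, lower=True)
    except np.linalg.LinAlgError:
        pass
    jit = start
    eye = np.eye(M.shape[0])
    while jit <= stop:
        try:
            c = cho_factor(M + jit * eye, lower=True)
            logger.info("coefficient matrix required jitter %.1e", jit)
            return c
        except np.linalg.LinAlgError:
            jit *= 10
    raise np.linalg.LinAlgError("singular MME coefficient matrix")


def solve_mme(spec: ModelSpec, vc: VarianceComponents) -> "BreedingValueResults":
    """Solve Henderson's mixed model equations and return full results.

    Returns BLUE b, BLUP a for every individual in K, and the
    inverse-coefficient-matrix diagonal d_i of the individual block, from
    which PEV/SEP/accuracy derive.
    """
    X, Z, y, K = spec.X, spec.Z, spec.y, spec.K
    p, q = spec.p, spec.q
    kdiag = np.diag(K.values).copy()
    if vc.sigma_a2 <= 1e-12 * max(vc.sigma_p2, 1e-300):
        # total shrinkage limit: a -> 0, b from OLS, PEV -> sigma_a^2 K_ii
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        dia = kdiag * (vc.sigma_a2 / vc.sigma_e2)
        return BreedingValueResults(spec, vc, beta, np.zeros(q), dia)
    lam = vc.lam
    Kinv = K.inv()
    lhs = np.empty((p + q, p + q))
    lhs[:p, :p] = X.T @ X
    lhs[:p, p:] = X.T @ Z
    lhs[p:, :p] = lhs[:p, p:].T
    lhs[p:, p:] = Z.T @ Z + Kinv * lam
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    c = _chol_jitter(lhs)
    sol = cho_solve(c, rhs)
    cinv = cho_solve(c, np.eye(p + q))
    dia = np.diag(cinv)[p:].copy()
    return BreedingValueResults(spec, vc, sol[:p], sol[p:], dia)


def accuracy(results: "BreedingValueResults",
             kii_convention: str = "matrix") -> np.ndarray:
    """Per-individual BLUP accuracy sqrt(1 - PEV_i / (sigma_a^2 K_ii)).

    ``kii_convention="matrix"`` takes K_ii from the actual diagonal of the
    supplied relationship matrix (self-consistent with a ~ N(0, K sigma_a^2));
    ``"one-plus-f"`` uses 1 + F_i with F_i decoded from the diagonal by the
    matrix method (the diploid-style convention). Values are clamped to
    [0, 1]; clamping is logged.
    """
    vc, K = results.vc, results.spec.K
    if kii_convention == "matrix":
        kii = np.diag(K.values).copy()
    elif kii_convention == "one-plus-f":
        kii = 1.0 + inbreeding_from_diagonal(K)
    else:
        raise ValueError(f"unknown kii convention {kii_convention!r}")
    if np.any(kii <= 0):
        raise ValueError("non-positive K_ii in accuracy denominator")
    if vc.sigma_a2 <= 0:
        return np.zeros(K.n)
    raw = 1.0 - results.pev / (vc.sigma_a2 * kii)
    clipped = np.clip(raw, 0.0, 1.0)
    n_clamped = int(np.sum((raw < 0) | (raw > 1)))
    if n_clamped:
        logger.info("accuracy clamped to [0,1] for %d individuals", n_clamped)
    return np.sqrt(clipped)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class BreedingValueModel:
    """Animal-model BLUP of breeding values for one trait.

    Parameters
    ----------
    spec : ModelSpec
        Assembled design; usually built via :meth:`from_tables`.

    Examples
    --------
    >>> model = BreedingValueModel.from_tables(phen, "fruit_load", K)
    >>> res = model.fit()
    >>> res.heritability, res.blups.head()
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    @classmethod
    def from_tables(cls, phen: PhenotypeTable, trait: str,
                    K: RelationshipMatrix,
                    blend: Optional[float] = None) -> "BreedingValueModel":
        """Assemble from a phenotype table and a relationship matrix.

        ``blend`` shrinks K towards the identity ((1-b)K + bI) before use —
        the standard guard for rank-deficient marker-based matrices.
        """
        if blend:
            K = K.blend(blend)
            logger.info("blended %s with %.3g * I before fitting",
                        K.method or "K", blend)
        return cls(assemble_model(phen, trait, K))

    def fit(self, tol: float = 1e-8, max_iter: int = 200,
            vc: Optional[VarianceComponents] = None) -> "BreedingValueResults":
        """REML variance components then MME solutions.

        Pass ``vc`` to force known variance components (skips REML).
        """
        if vc is None:
            vc = reml_fit(self.spec, tol=tol, max_iter=max_iter)
        return solve_mme(self.spec, vc)


class BreedingValueResults:
    """Fitted animal model: variance components, BLUE/BLUP, PEV, accuracy."""

    def __init__(self, spec: ModelSpec, vc: VarianceComponents,
                 fixed_effects: np.ndarray, blup: np.ndarray,
                 lhs_inv_diag: np.ndarray):
        self.spec = spec
        self.vc = vc
        self.fixed_effects = pd.Series(fixed_effects, index=spec.x_names,
                                       name="estimate")
        self.blups = pd.Series(blup, index=spec.K.ids, name="blup")
        self.lhs_inv_diag = np.asarray(lhs_inv_diag, dtype=float)

    # -- derived quantities -----------------------------------------------
    @property
    def pev(self) -> np.ndarray:
        """Prediction error variance PEV_i = d_i sigma_e^2."""
        return self.lhs_inv_diag * self.vc.sigma_e2

    @property
    def sep(self) -> np.ndarray:
        """Standard error of prediction sqrt(PEV_i)."""
        return np.sqrt(self.pev)

    def accuracy(self, kii_convention: str = "matrix") -> pd.Series:
        return pd.Series(accuracy(self, kii_convention),
                         index=self.spec.K.ids, name="accuracy")

    @property
    def heritability(self) -> float:
        return self.vc.h2

    @property
    def lam(self) -> float:
        return self.vc.lam

    def by_id(self) -> pd.DataFrame:
        """Tidy per-individual table: blup, pev, sep, accuracy."""
        return pd.DataFrame({
            "blup": self.blups,
            "pev": pd.Series(self.pev, index=self.spec.K.ids),
            "sep": pd.Series(self.sep, index=self.spec.K.ids),
            "accuracy": self.accuracy(),
        })

    def to_dict(self) -> dict:
        return {
            "trait": self.spec.trait,
            "matrix_method": self.spec.K.method,
            "sigma_a2": self.vc.sigma_a2,
            "sigma_e2": self.vc.sigma_e2,
            "h2": self.heritability,
            "loglik": self.vc.loglik,
            "converged": self.vc.converged,
            "fixed_effects": self.fixed_effects.to_dict(),
            "individuals": self.by_id().to_dict(orient="index"),
        }

    def summary(self) -> str:
        vc = self.vc
        acc = self.accuracy()
        lines = [
            "Animal-model BLUP results",
            "=" * 60,
            f"trait: {self.spec.trait}   relationship: "
            f"{self.spec.K.method or '?'}"
            + (f" (w={self.spec.K.w})" if self.spec.K.w is not None else ""),
            f"records: {self.spec.n}   individuals: {self.spec.q}   "
            f"fixed effects: {self.spec.p}",
            "-" * 60,
            f"sigma_a^2 = {vc.sigma_a2:.6g}  (SE {vc.se[0]:.3g})",
            f"sigma_e^2 = {vc.sigma_e2:.6g}  (SE {vc.se[1]:.3g})",
            f"h2_NS     = {vc.h2:.4f}   lambda = {vc.lam:.4g}",
            f"REML logL = {vc.loglik:.4f}   iterations = {vc.n_iterations}"
            f"   converged = {vc.converged}"
            + ("   [sigma_a^2 at boundary]" if vc.boundary else ""),
            "-" * 60,
            "fixed effects:",
        ]
        for name, est in self.fixed_effects.items():
            lines.append(f"  {name:<12s} {est:>12.6g}")
        lines += [
            "-" * 60,
            f"mean accuracy = {float(acc.mean()):.4f} "
            f"(min {float(acc.min()):.4f}, max {float(acc.max()):.4f})",
        ]
        return "\n".join(lines)
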