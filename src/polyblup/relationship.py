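"""Additive relationship matrices (pedigree- or marker-based).

A :class:`RelationshipMatrix` is ploidy x coancestry: the variance-covariance
scaffold K of the additive genetic effect a ~ N(0, K sigma_a^2). The method
tag records how it was built (A2, A4, A4w, G2, G4), which also fixes how the
diagonal maps to an inbreeding coefficient: diag = 1 + F for the disomic
matrices and realized G, diag = 1 + 3F for the tetrasomic pedigree matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

__all__ = ["RelationshipMatrix", "inbreeding_from_diagonal",
           "read_matrix", "write_matrix"]

#: methods whose diagonal is 1 + 3F (tetrasomic pedigree expectation)
_TETRASOMIC_PEDIGREE = {"A4", "A4w"}


@dataclass
class RelationshipMatrix:
    ids: list
    values: np.ndarray
    method: str = ""
    ploidy: int = 4
    w: Optional[float] = None  # double reduction, pedigree methods only

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids) -> "RelationshipMatrix":
        idx = [self.ids.index(i) for i in ids]
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                  self.method, self.ploidy, self.w)

    def blend(self, alpha: float = 0.01) -> "RelationshipMatrix":
        """Shrink towards the identity: (1-alpha) K + alpha I.

        Standard regularisation before inverting a marker-based K whose rank
        is limited by the marker count.
        """
        v = (1 - alpha) * self.values + alpha * np.eye(self.n)
        return RelationshipMatrix(list(self.ids), v, self.method,
                                  self.ploidy, self.w)

    def inbreeding(self) -> np.ndarray:
        return inbreeding_from_diagonal(self)

    def is_psd(self, rtol: float = 1e-8) -> bool:
        ev = eigh(self.values, eigvals_only=True)
        return ev[0] >= -rtol * max(ev[-1], 1.0)

    def inv(self, jitter_start: float = 1e-10, jitter_max: float = 1e-6
            ) -> np.ndarray:
        """Dense inverse via Cholesky with escalating diagonal jitter."""
        v = self.values
        eye = np.eye(self.n)
        try:
            return cho_solve(cho_factor(v, lower=True), eye)
        except np.linalg.LinAlgError:
            pass
        jit = jitter_start
        while jit <= jitter_max:
            try:
                return cho_solve(cho_factor(v + jit * eye, lower=True), eye)
            except np.linalg.LinAlgError:
                jit *= 10
        raise np.linalg.LinAlgError(
            f"{self.method or 'relationship'} matrix not invertible even "
            f"with jitter up to {jitter_max:g}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def inbreeding_from_diagonal(K: RelationshipMatrix) -> np.ndarray:
    """Per-individual inbreeding coefficient implied by the diagonal.

    A2 and the realized G matrices use diag = 1 + F; the tetrasomic pedigree
    matrices A4/A4w use diag = 1 + 3F (self-coancestry (1+3F)/4 scaled by 4).
    """
    d = np.diag(K.values)
    if K.method in _TETRASOMIC_PEDIGREE:
        return (d - 1.0) / 3.0
    return d - 1.0


def read_matrix(path, method: str = "", ploidy: int = 4,
                w: Optional[float] = None) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(list(df.index.astype(str)),
                              df.to_numpy(dtype=float), method, ploidy, w)


def write_matrix(K: RelationshipMatrix, path) -> None:
    K.to_frame().to_csv(path)
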