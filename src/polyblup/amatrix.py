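"""Pedigree-based (probabilistic) additive relationship matrices.

Two recursions over a generation-ordered pedigree:

* ``build_A2`` — the classical disomic numerator relationship matrix
  (Henderson's tabular method): treats every individual as diploid,
  a_kj = (a_sj + a_dj)/2 and a_kk = 1 + a_sd/2.

* ``build_A4`` — the tetrasomic matrix A = 4*Theta for even-ploidy
  inheritance with double reduction omega: with probability omega a gamete
  carries two copies of one parental allele (sister chromatids migrating to
  the same pole of a multivalent), which inflates identity-by-descent within
  gametes and hence inbreeding. Founders have diagonal exactly 1 under both
  conventions; the tetrasomic diagonal is 1 + 3F.

A missing parent is treated as a unique, non-inbred founder unrelated to
everything else (standard numerator-relationship convention).
"""

from __future__ import annotations

import numpy as np

from .pedigree import Pedigree
from .relationship import RelationshipMatrix

__all__ = ["build_A2", "build_A4"]


def build_A2(ped: Pedigree) -> RelationshipMatrix:
    """Disomic numerator relationship matrix by the tabular method."""
    n = ped.n
    par = np.asarray(ped.parent_indices(), dtype=np.int64).reshape(n, 2)
    A = np.zeros((n, n))
    for k in range(n):
        s, d = par[k]
        row = np.zeros(k)
        if s >= 0:
            row += 0.5 * A[s, :k]
        if d >= 0:
            row += 0.5 * A[d, :k]
        A[k, :k] = row
        A[:k, k] = row
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[k, k] = 1.0 + 0.5 * asd
    return RelationshipMatrix(ped.ids, A, method="A2", ploidy=2)


def build_A4(ped: Pedigree, w: float) -> RelationshipMatrix:
    """Tetrasomic numerator relationship matrix A = 4*Theta with double
    reduction ``w``.

    The recursion tracks, per individual, the coancestry row and the
    internal identity F_k = P(two *distinct* allele copies of k are IBD).
    An offspring's four alleles are two gametes of two alleles each; a pair
    of distinct alleles falls within the sire gamete, within the dam gamete,
    or across gametes with probabilities 1/6, 1/6, 4/6, giving

        F_k = (phi_s + phi_d)/6 + (2/3) theta_sd,
        phi_p = w + (1 - w) F_p        (within-gamete IBD),

    cross-coancestry theta_kj = (theta_sj + theta_dj)/2 (a random allele
    from a gamete of p is a uniformly random allele of p, with or without
    double reduction), and self-coancestry theta_kk = (1 + 3 F_k)/4.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"double-reduction coefficient w={w} outside [0, 1]")
    n = ped.n
    par = np.asarray(ped.parent_indices(), dtype=np.int64).reshape(n, 2)
    theta = np.zeros((n, n))
    F = np.zeros(n)
    for k in range(n):
        s, d = par[k]
        if s < 0 and d < 0:
            F[k] = 0.0
            theta[k, k] = 0.25
            continue
        row = np.zeros(k)
        if s >= 0:
            row += 0.5 * theta[s, :k]
        if d >= 0:
            row += 0.5 * theta[d, :k]
        theta[k, :k] = row
        theta[:k, k] = row
        phi_s = w + (1.0 - w) * (F[s] if s >= 0 else 0.0)
        phi_d = w + (1.0 - w) * (F[d] if d >= 0 else 0.0)
        tsd = theta[s, d] if (s >= 0 and d >= 0) else 0.0
        F[k] = (phi_s + phi_d) / 6.0 + (2.0 / 3.0) * tsd
        theta[k, k] = (1.0 + 3.0 * F[k]) / 4.0
    method = "A4" if w == 0.0 else "A4w"
    return RelationshipMatrix(ped.ids, 4.0 * theta, method=method,
                              ploidy=4, w=w)
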