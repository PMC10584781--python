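"""Realized (marker-based) additive relationship matrices.

``build_G4`` is the VanRaden cross-product estimator adapted to tetraploid
allele dosage: centre dosages by 4p and normalise by the summed
Hardy-Weinberg dosage variance sum_j 4 p_j (1 - p_j), so the expected mean
diagonal in an unstructured population is 1.

``build_G2`` is the Yang et al. (GCTA) estimator on pseudo-diploid codes,
with the bias-adjusted diagonal 1 + (x^2 - (1+2p)x + 2p^2) / (2p(1-p))
averaged over markers — an estimate of 1 + F that can legitimately fall
below 1 for outbred individuals.

Allele frequencies come from the supplied matrix, i.e. the full genotyped
set, not a training subset.
"""

from __future__ import annotations

import numpy as np

from .dosage import DosageMatrix
from .relationship import RelationshipMatrix

__all__ = ["build_G4", "build_G2"]


def build_G4(d4: DosageMatrix) -> RelationshipMatrix:
    """Tetraploid VanRaden-type genomic relationship matrix.

    G = W W' / (4 sum_j p_j (1-p_j)) with W = M - 4p, M the n x m dosage
    matrix. Requires polymorphic markers (denominator > 0).
    """
    if d4.ploidy != 4:
        raise ValueError("build_G4 requires tetraploid dosages")
    p = d4.allele_freq
    denom = 4.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero HWE variance")
    W = d4.dosage - 4.0 * p[None, :]
    G = (W @ W.T) / denom
    return RelationshipMatrix(list(d4.ids), G, method="G4", ploidy=4)


def build_G2(d2: DosageMatrix) -> RelationshipMatrix:
    """Yang et al. genomic relationship matrix for (pseudo-)diploid codes.

    Off-diagonal: mean over markers of
    (x_ij - 2p_j)(x_kj - 2p_j) / (2 p_j (1-p_j)).
    Diagonal: 1 + mean over markers of
    (x_ij^2 - (1+2p_j) x_ij + 2 p_j^2) / (2 p_j (1-p_j)).
    Monomorphic markers must be filtered beforehand.
    """
    if d2.ploidy != 2:
        raise ValueError("build_G2 requires diploid (or pseudo-diploid) input")
    p = d2.allele_freq
    if np.any((p <= 0) | (p >= 1)):
        j = int(np.argmax((p <= 0) | (p >= 1)))
        raise ValueError(
            f"monomorphic marker {d2.marker_ids[j]!r} present; apply a maf "
            "filter before building G2")
    x = d2.dosage.astype(float)
    het = 2.0 * p * (1.0 - p)
    W = (x - 2.0 * p[None, :]) / np.sqrt(het)[None, :]
    m = d2.m
    G = (W @ W.T) / m
    diag = 1.0 + np.mean(
        (x * x - (1.0 + 2.0 * p)[None, :] * x + (2.0 * p * p)[None, :]) / het,
        axis=1)
    np.fill_diagonal(G, diag)
    return RelationshipMatrix(list(d2.ids), G, method="G2", ploidy=2)
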