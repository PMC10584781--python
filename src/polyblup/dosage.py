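"""Allele-dosage matrices for diploid and tetraploid genotypes.

A :class:`DosageMatrix` holds integer alternate-allele counts (0..ploidy) per
individual x biallelic marker, with per-marker allele frequencies derived as
column mean / ploidy. Tetraploid calls follow the five dosage classes
AAAA=0, AAAB=1, AABB=2, ABBB=3, BBBB=4; :func:`recode_pseudo_diploid`
collapses the three heterozygote classes to a single diploid-style
heterozygote (0->0, {1,2,3}->1, 4->2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DosageMatrix", "DosageError", "MarkerFilterReport",
    "read_dosage", "write_dosage", "recode_pseudo_diploid", "maf_filter",
]


class DosageError(ValueError):
    """Out-of-range, non-integer or structurally invalid dosage data."""


@dataclass
class DosageMatrix:
    """Individuals x markers integer allele-dosage matrix.

    Attributes
    ----------
    ids : list of str
        Individual identifiers (rows).
    marker_ids : list of str
        Marker identifiers (columns).
    dosage : (n, m) int ndarray
        Alternate-allele counts in [0, ploidy].
    ploidy : int
        2 or 4.
    """

    ids: list
    marker_ids: list
    dosage: np.ndarray
    ploidy: int = 4

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        d = np.asarray(self.dosage)
        if d.ndim != 2 or d.shape != (len(self.ids), len(self.marker_ids)):
            raise DosageError("dosage shape does not match ids x marker_ids")
        if self.ploidy not in (2, 4):
            raise DosageError(f"unsupported ploidy {self.ploidy}")
        if not np.issubdtype(d.dtype, np.integer):
            if not np.all(np.isfinite(d)) or np.any(d != np.round(d)):
                bad = np.argwhere(~np.isfinite(d) | (d != np.round(d)))[0]
                raise DosageError(
                    f"non-integer dosage at row {self.ids[bad[0]]!r} "
                    f"marker {self.marker_ids[bad[1]]!r}")
            d = d.astype(np.int64)
        if d.size and (d.min() < 0 or d.max() > self.ploidy):
            bad = np.argwhere((d < 0) | (d > self.ploidy))[0]
            raise DosageError(
                f"dosage outside [0, {self.ploidy}] at row "
                f"{self.ids[bad[0]]!r} marker {self.marker_ids[bad[1]]!r}")
        self.dosage = d.astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.marker_ids)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency p_j = column mean / ploidy."""
        return self.dosage.mean(axis=0) / self.ploidy

    def subset(self, ids=None, markers=None) -> "DosageMatrix":
        ridx = slice(None) if ids is None else [self.ids.index(i) for i in ids]
        cidx = (slice(None) if markers is None
                else [self.marker_ids.index(m) for m in markers])
        new_ids = self.ids if ids is None else list(ids)
        new_mk = self.marker_ids if markers is None else list(markers)
        return DosageMatrix(new_ids, new_mk, self.dosage[ridx][:, cidx],
                            self.ploidy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.ids,
                            columns=self.marker_ids)


@dataclass
class MarkerFilterReport:
    """Bookkeeping for a minor-allele-frequency filtering pass."""

    markers_in: int
    markers_removed_maf: int
    maf_threshold: float
    removed_ids: list = field(default_factory=list)

    @property
    def markers_out(self) -> int:
        return self.markers_in - self.markers_removed_maf

    def to_dict(self) -> dict:
        return {
            "markers_in": self.markers_in,
            "markers_removed_maf": self.markers_removed_maf,
            "markers_out": self.markers_out,
            "maf_threshold": self.maf_threshold,
        }


def recode_pseudo_diploid(d4: DosageMatrix) -> DosageMatrix:
    """Collapse tetraploid dosages to pseudo-diploid codes.

    All heterozygote classes become one class: 0 (AAAA=AA) -> 0,
    {1 (AAAB), 2 (AABB), 3 (ABBB)} -> 1 (AB), 4 (BBBB) -> 2 (BB).
    """
    if d4.ploidy != 4:
        raise DosageError("pseudo-diploid recoding requires tetraploid input")
    lut = np.array([0, 1, 1, 1, 2], dtype=np.int64)
    return DosageMatrix(list(d4.ids), list(d4.marker_ids), lut[d4.dosage],
                        ploidy=2)


def maf_filter(d: DosageMatrix, threshold: float):
    """Remove low-information markers: minor-allele frequency below
    ``threshold``, or zero genotype variance (constant column).

    The variance rule catches columns that frequency alone misses — e.g. a
    tetraploid marker whose heterozygote classes collapse to a constant
    pseudo-diploid 1 sits at p = 0.5 yet carries no information. Returns
    (filtered DosageMatrix, MarkerFilterReport). A monomorphic marker
    (p = 0 or 1) is removed for any threshold > 0.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("maf threshold must lie in [0, 0.5]")
    p = d.allele_freq
    keep = np.minimum(p, 1 - p) >= threshold
    if threshold > 0:
        keep &= d.dosage.var(axis=0) > 0
    removed = [m for m, k in zip(d.marker_ids, keep) if not k]
    report = MarkerFilterReport(d.m, int((~keep).sum()), threshold, removed)
    kept = [m for m, k in zip(d.marker_ids, keep) if k]
    out = DosageMatrix(list(d.ids), kept, d.dosage[:, keep], d.ploidy)
    logger.info("maf filter %.3g: %d of %d markers removed", threshold,
                report.markers_removed_maf, report.markers_in)
    return out, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dosage(path, format: str = "csv", ploidy: int = 4,
                vcf_field: str = "DS") -> DosageMatrix:
    """Read an allele-dosage matrix from CSV or VCF.

    CSV: individuals as rows (first column = id), markers as columns.
    VCF: one sample column per individual; dosage from FORMAT key
    ``vcf_field`` (default "DS", rounded to nearest integer) or, with
    ``vcf_field="GT"``, from counting alternate alleles in ploidy-4 calls.
    Missing entries are imputed per marker to the rounded mean dosage; the
    imputation count is logged.
    """
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        vals = df.to_numpy(dtype=float)
        ids, markers = list(df.index.astype(str)), list(df.columns.astype(str))
    elif format == "vcf":
        ids, markers, vals = _read_vcf_dosage(path, vcf_field, ploidy)
    else:
        raise ValueError(f"unsupported dosage format {format!r}")

    miss = ~np.isfinite(vals)
    if miss.any():
        if miss.all(axis=0).any():
            j = int(np.argmax(miss.all(axis=0)))
            raise DosageError(f"marker {markers[j]!r} has no called dosages")
        colmean = np.nanmean(np.where(miss, np.nan, vals), axis=0)
        fill = np.round(colmean)
        vals = np.where(miss, fill[None, :], vals)
        logger.info("imputed %d missing dosages to per-marker rounded means",
                    int(miss.sum()))
    return DosageMatrix(ids, markers, vals, ploidy)


def _read_vcf_dosage(path, field, ploidy):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    markers, rows = [], []
    for var in vcf:
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append(name)
        if field == "GT":
            # count alternate alleles over the ploidy-4 call; -1 = missing
            gt = np.asarray(var.genotype.array())[:, :ploidy]
            miss = (gt < 0).any(axis=1)
            dose = np.where(miss, np.nan, (gt > 0).sum(axis=1).astype(float))
        else:
            ds = var.format(field)
            if ds is None:
                raise DosageError(
                    f"FORMAT field {field!r} absent at {name}")
            ds = np.asarray(ds, dtype=float).reshape(len(ids), -1)[:, 0]
            dose = np.where(np.isfinite(ds), np.round(ds), np.nan)
        rows.append(dose)
    vcf.close()
    return ids, markers, np.asarray(rows, dtype=float).T


def write_dosage(d: DosageMatrix, path) -> None:
    """Write as labelled CSV (rows = ids, columns = marker ids)."""
    d.to_frame().to_csv(path)


def write_dosage_vcf(d: DosageMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT (unphased) and DS per sample."""
    n, ploidy = d.n, d.ploidy
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(d.ids) + "\n")
        for j, mk in enumerate(d.marker_ids):
            cells = []
            for i in range(n):
                k = int(d.dosage[i, j])
                gt = "/".join(["1"] * k + ["0"] * (ploidy - k))
                cells.append(f"{gt}:{k}")
            fh.write(f"1\t{j + 1}\t{mk}\tA\tB\t.\tPASS\t.\tGT:DS\t"
                     + "\t".join(cells) + "\n")
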