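"""Pedigree container: ordered trio records with sex.

A pedigree is a list of (id, sire, dam, sex) records. Unknown parents may be
coded as the empty string, "0", "NA" or NaN in input files; internally they
are normalised to ``None``. Individuals are kept in a *generation order* — a
stable topological order in which every known parent precedes its offspring —
which is what the tabular relationship-matrix recursions and the gene-dropping
simulator require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = ["Pedigree", "PedigreeError", "read_pedigree", "write_pedigree"]

#: input spellings accepted for an unknown parent
_MISSING_CODES = {"", "0", "NA", "NAN", "NONE", "."}

_SEX_CODES = {
    "F": "F", "FEMALE": "F", "f": "F",
    "M": "M", "MALE": "M", "m": "M",
}


class PedigreeError(ValueError):
    """Malformed pedigree: duplicate ids, cycles, or unknown references."""


def _norm_parent(x) -> Optional[str]:
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return None
    s = str(x).strip()
    if s.upper() in _MISSING_CODES:
        return None
    return s


def _norm_sex(x) -> str:
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return "U"
    return _SEX_CODES.get(str(x).strip(), "U")


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    records : list of (id, sire, dam, sex)
        Trio records in any order; parents referenced but not listed are
        added as founders. ``sire``/``dam`` may be None; sex is one of
        ``"F"``, ``"M"``, ``"U"``.
    """

    records: list = field(default_factory=list)

    def __post_init__(self):
        rec = []
        for r in self.records:
            iid, sire, dam, sex = (list(r) + ["U"])[:4]
            rec.append((str(iid).strip(), _norm_parent(sire), _norm_parent(dam),
                        _norm_sex(sex)))
        ids = [r[0] for r in rec]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise PedigreeError(f"duplicate individual id {dup!r}")
        # implicit founders: parents never listed as individuals
        known = set(ids)
        for _, s, d, _ in rec:
            for p in (s, d):
                if p is not None and p not in known:
                    rec.append((p, None, None, "U"))
                    known.add(p)
        self.records = self._toposort(rec)
        self._index = {r[0]: i for i, r in enumerate(self.records)}

    @staticmethod
    def _toposort(rec):
        # stable Kahn: repeatedly emit, in input order, individuals whose
        # parents are already emitted — deterministic given input order
        pending = list(rec)
        out, placed = [], set()
        while pending:
            progress = False
            remain = []
            for r in pending:
                s, d = r[1], r[2]
                if (s is None or s in placed) and (d is None or d in placed):
                    out.append(r)
                    placed.add(r[0])
                    progress = True
                else:
                    remain.append(r)
            if not progress:
                raise PedigreeError(
                    f"pedigree cycle detected involving id {remain[0][0]!r}")
            pending = remain
        return out

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> list:
        return [r[0] for r in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def sex(self, iid: str) -> str:
        return self.records[self._index[iid]][3]

    def parents(self, iid: str):
        r = self.records[self._index[iid]]
        return r[1], r[2]

    def parent_indices(self):
        """(n, 2) array-like of parent positions, -1 for missing."""
        out = []
        for _, s, d, _ in self.records:
            out.append((self._index[s] if s is not None else -1,
                        self._index[d] if d is not None else -1))
        return out

    def founders(self) -> list:
        return [r[0] for r in self.records if r[1] is None and r[2] is None]

    def females(self) -> list:
        return [r[0] for r in self.records if r[3] == "F"]

    def males(self) -> list:
        return [r[0] for r in self.records if r[3] == "M"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["id", "sire", "dam", "sex"])

    def __contains__(self, iid) -> bool:
        return iid in self._index

    def __len__(self) -> int:
        return self.n


def read_pedigree(path, format: str = "csv") -> Pedigree:
    """Read a pedigree CSV with columns id, sire, dam [, sex].

    Rows may appear in any order; the returned pedigree is generation-ordered.
    Unknown parents may be blank, "0", "NA" or ".".
    """
    if format != "csv":
        raise ValueError(f"unsupported pedigree format {format!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    for need in ("id", "sire", "dam"):
        if need not in cols:
            raise PedigreeError(f"pedigree file missing column {need!r}")
    sex = df[cols["sex"]] if "sex" in cols else ["U"] * len(df)
    recs = list(zip(df[cols["id"]], df[cols["sire"]], df[cols["dam"]], sex))
    return Pedigree(recs)


def write_pedigree(ped: Pedigree, path) -> None:
    df = ped.to_frame().copy()
    df["sire"] = df["sire"].fillna("")
    df["dam"] = df["dam"].fillna("")
    df.to_csv(path, index=False)
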