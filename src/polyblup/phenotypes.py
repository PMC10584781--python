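"""Long-format phenotype records: (individual, year, trait, value).

Phenotypes in a dioecious crop are sex-limited — only female vines bear
fruit — so the table typically covers a subset of the pedigree. Records are
unique on (id, year, trait) and every id must exist in the pedigree against
which the table is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PhenotypeTable", "PhenotypeError", "read_phenotypes",
           "write_phenotypes"]


class PhenotypeError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    """Validated long-format phenotype table.

    ``data`` has columns id (str), year (int), trait (str), value (float).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        need = ["id", "year", "trait", "value"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise PhenotypeError(f"phenotype table missing columns {missing}")
        df["id"] = df["id"].astype(str)
        df["trait"] = df["trait"].astype(str)
        try:
            df["year"] = df["year"].astype(int)
            df["value"] = df["value"].astype(float)
        except (TypeError, ValueError) as e:
            raise PhenotypeError(f"non-numeric year or value: {e}") from e
        if not np.all(np.isfinite(df["value"])):
            raise PhenotypeError("non-finite phenotype value")
        dup = df.duplicated(subset=["id", "year", "trait"])
        if dup.any():
            r = df[dup].iloc[0]
            raise PhenotypeError(
                f"duplicate record ({r['id']}, {r['year']}, {r['trait']})")
        self.data = df[need].reset_index(drop=True)

    def validate_against(self, ped) -> "PhenotypeTable":
        unknown = [i for i in self.data["id"].unique() if i not in ped]
        if unknown:
            raise PhenotypeError(
                f"phenotyped id(s) absent from pedigree: {unknown[:5]}")
        return self

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise PhenotypeError(f"trait {trait!r} not present")
        return sub.reset_index(drop=True)

    def phenotyped_ids(self, trait: str) -> list:
        return list(dict.fromkeys(self.for_trait(trait)["id"]))

    def mean_by_id(self, trait: str) -> pd.Series:
        """Per-individual phenotype averaged over years (CV observed value)."""
        sub = self.for_trait(trait)
        return sub.groupby("id", sort=False)["value"].mean()

    def __len__(self) -> int:
        return len(self.data)


def read_phenotypes(path, pedigree=None) -> PhenotypeTable:
    """Read long-format CSV (id, year, trait, value); optionally check ids
    against a Pedigree."""
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    tab = PhenotypeTable(df)
    if pedigree is not None:
        tab.validate_against(pedigree)
    return tab


def write_phenotypes(tab: PhenotypeTable, path) -> None:
    tab.data.to_csv(path, index=False)
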