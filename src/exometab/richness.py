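"""Chemical richness and FIELD/HYDRO Venn overlaps per species."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from exometab.vocab import SPECIES, group_key


@dataclass
class VennReport:
    species: str
    n_field_only: int
    n_hydro_only: int
    n_shared: int

    @property
    def n_field_total(self) -> int:
        return self.n_field_only + self.n_shared

    @property
    def n_hydro_total(self) -> int:
        return self.n_hydro_only + self.n_shared

    @property
    def fold_field_over_hydro(self) -> float:
        """Richness ratio FIELD/HYDRO; NaN when the HYDRO count is zero."""
        if self.n_hydro_total == 0:
            return math.nan
        return self.n_field_total / self.n_hydro_total

    def to_dict(self) -> dict:
        fold = self.fold_field_over_hydro
        return {
            "species": self.species,
            "n_field_only": self.n_field_only,
            "n_hydro_only": self.n_hydro_only,
            "n_shared": self.n_shared,
            "n_field_total": self.n_field_total,
            "n_hydro_total": self.n_hydro_total,
            "fold_field_over_hydro": fold,
            "fold_rounded": round(fold, 1) if not math.isnan(fold) else math.nan,
        }


def venn_counts(presence: pd.DataFrame, species: str) -> VennReport:
    """Unique/shared feature counts between the two cultivation conditions."""
    for cond in ("FIELD", "HYDRO"):
        if group_key(species, cond) not in presence.columns:
            raise ValueError(f"presence matrix lacks group {group_key(species, cond)}")
    f = presence[group_key(species, "FIELD")].astype(bool)
    h = presence[group_key(species, "HYDRO")].astype(bool)
    return VennReport(
        species=species,
        n_field_only=int((f & ~h).sum()),
        n_hydro_only=int((~f & h).sum()),
        n_shared=int((f & h).sum()),
    )


def venn_report_table(presence: pd.DataFrame) -> pd.DataFrame:
    """One VennReport row per species."""
    return pd.DataFrame([venn_counts(presence, sp).to_dict() for sp in SPECIES])


def richness_table(presence: pd.DataFrame) -> pd.Series:
    """Feature count per group: column sums of the binary presence matrix."""
    return presence.astype(bool).sum(axis=0)
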