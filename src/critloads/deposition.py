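"""Base-cation emission inventory aggregation.

Bc deposition itself enters the critical-load pipeline as a gridded input
layer (`bc_dep`, keq/ha/yr of Ca+Mg+K); atmospheric transport is out of
scope. What is implemented here is the standalone inventory step feeding such
a transport model: per-species base-cation emissions as the PM-emission-
weighted sum of species mass fractions over provinces and sectors,

    Bc_k = sum_{i,j} PM_{i,j} * omega_{k,i,j}

with i provinces, j sectors and k the Bc species (Ca, Mg, K; Na may be
reported but is excluded from the deposition layer because plants do not
take it up).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import ConfigurationError, InvalidInputError

__all__ = ["EmissionTable", "bc_emissions", "bc_emissions_by_province"]

BC_SPECIES = ("Ca", "Mg", "K", "Na")


@dataclass
class EmissionTable:
    """PM emissions by (province, sector) plus species mass fractions.

    ``pm``: columns province, sector, pm_kt (kt/yr).
    ``fractions``: columns province, sector, species, omega (mass fraction).
    """

    pm: pd.DataFrame
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.pm["pm_kt"] < 0).any():
            raise InvalidInputError("PM emissions must be >= 0")
        om = self.fractions["omega"]
        if ((om < 0) | (om > 1)).any():
            raise InvalidInputError("mass fractions must lie in [0, 1]")
        sums = self.fractions.groupby(["province", "sector"])["omega"].sum()
        bad = sums[sums > 1.0 + 1e-12]
        if len(bad):
            raise InvalidInputError(
                f"species fractions exceed 1 for {list(bad.index)}"
            )

    @classmethod
    def from_csv(cls, pm_path, fractions_path) -> "EmissionTable":
        return cls(pd.read_csv(pm_path), pd.read_csv(fractions_path))


def bc_emissions_by_province(t: EmissionTable, species: str) -> pd.Series:
    """Per-province emission of one Bc species (kt/yr), summed over sectors."""
    if species not in BC_SPECIES:
        raise InvalidInputError(f"unknown Bc species {species!r}")
    frac = t.fractions[t.fractions["species"] == species]
    merged = t.pm.merge(frac, on=["province", "sector"], how="left")
    missing = merged[merged["omega"].isna() & (merged["pm_kt"] > 0)]
    if len(missing):
        keys = list(zip(missing["province"], missing["sector"]))
        raise ConfigurationError(
            f"missing omega({species}) for PM rows: {keys}"
        )
    merged["omega"] = merged["omega"].fillna(0.0)
    out = (merged["pm_kt"] * merged["omega"]).groupby(merged["province"]).sum()
    return out.rename(f"{species}_kt")


def bc_emissions(t: EmissionTable, species: str) -> float:
    """National total emission of one Bc species (kt/yr)."""
    return float(bc_emissions_by_province(t, species).sum())
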