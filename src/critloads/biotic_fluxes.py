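"""Biological sinks of the mass balance: plant uptake, N immobilization,
denitrification fraction.

Net growth uptake removes the element content of the harvested biomass
fraction of NPP; long-term nitrogen immobilization is the soil N pool divided
by the soil's genetic age; the denitrification fraction f_de comes from the
forest-type observation table for forests and from the drainage scale (with a
coarse-soil override) elsewhere. All fluxes are returned in keq/ha/yr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    FOREST_FDE,
    GlobalConstants,
    InvalidInputError,
    ConfigurationError,
    VegParams,
    drainage_to_fde,
    lookup_soil_age,
)

__all__ = [
    "UptakeInputs",
    "NitrogenPool",
    "net_uptake",
    "n_immobilization",
    "denitrification_fraction",
    "mass_flux_to_keq",
]

M2_PER_HA = 1.0e4


def mass_flux_to_keq(mass_g_per_m2_yr, equivalent_weight_g_per_eq):
    """g element / m2 / yr  ->  keq / ha / yr (exactly invertible)."""
    return np.asarray(mass_g_per_m2_yr) * M2_PER_HA \
        / equivalent_weight_g_per_eq / 1000.0


@dataclass(frozen=True)
class UptakeInputs:
    """NPP (g dry matter / m2 / yr) plus the cell's vegetation parameters."""

    npp: float
    veg: VegParams

    def __post_init__(self) -> None:
        if self.npp < 0:
            raise InvalidInputError(f"NPP must be >= 0, got {self.npp}")


@dataclass(frozen=True)
class NitrogenPool:
    """Areal soil nitrogen pool (kg N/m2) and soil age (years)."""

    n_areal: float
    soil_age: float

    def __post_init__(self) -> None:
        if self.n_areal < 0:
            raise InvalidInputError("soil N pool must be >= 0")
        if not self.soil_age > 0:
            raise InvalidInputError("soil age must be > 0")

    @classmethod
    def from_age_class(cls, n_areal: float, soil_age_class: str) -> "NitrogenPool":
        return cls(n_areal, lookup_soil_age(soil_age_class))


def net_uptake(u: UptakeInputs, element: str,
               constants: GlobalConstants | None = None) -> float:
    """Net removal of N or Bc by plant growth, keq/ha/yr.

    NPP x p_harvest x element content gives a mass flux (g/m2/yr), converted
    to charge equivalents with the element's equivalent weight. Cropland and
    bare cells remove nothing (they are masked downstream anyway).
    """
    c = constants or GlobalConstants()
    if element == "N":
        content, eqw = u.veg.c_n, c.equivalent_weights["N"]
    elif element == "Bc":
        content, eqw = u.veg.c_bc, c.bc_equivalent_weight
    else:
        raise ConfigurationError(f"unknown uptake element {element!r}")
    if u.veg.is_cropland_or_bare:
        return 0.0
    return float(mass_flux_to_keq(u.npp * u.veg.p_harvest * content, eqw))


def n_immobilization(p: NitrogenPool,
                     constants: GlobalConstants | None = None) -> float:
    """Long-term N immobilization: soil N pool / soil age, as keq/ha/yr."""
    c = constants or GlobalConstants()
    mass_g_per_m2_yr = p.n_areal * 1000.0 / p.soil_age
    return float(mass_flux_to_keq(mass_g_per_m2_yr, c.equivalent_weights["N"]))


def denitrification_fraction(veg: VegParams, drainage, ssa,
                             constants: GlobalConstants | None = None,
                             ) -> tuple[float, bool]:
    """Denitrification fraction f_de in [0, 0.8] and a coarse-override flag.

    Forest cells take the observation-based value of their forest class
    (tropical broadleaf 0.65, temperate coniferous 0.20, temperate broadleaf
    0.25, subtropical 0.35). Other cells follow the drainage scale, except
    that coarse soils (SSA < 2e6 m2/m3) are capped at f_de = 0.1 to avoid
    overestimating denitrification in freely draining substrates; the
    override applies only to the drainage-based pathway.
    """
    c = constants or GlobalConstants()
    if ssa < 0:
        raise InvalidInputError("SSA must be >= 0")
    if veg.forest_class != "non_forest":
        try:
            return FOREST_FDE[veg.forest_class], False
        except KeyError:
            raise ConfigurationError(
                f"no f_de for forest class {veg.forest_class!r}"
            ) from None
    if ssa < c.ssa_coarse_threshold:
        return c.fde_coarse_value, True
    return drainage_to_fde(drainage), False
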