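"""Parameter tables and global constants of the SMB critical-load method.

Everything the method looks up per class code lives here: the gibbsite-constant
ladder keyed on soil organic matter, the three soil-age classes used for
nitrogen immobilization, the seven-level soil-drainage scale mapped onto the
denitrification fraction, per-soil-type baseline weathering rates, and
per-vegetation-type biomass/element parameters and critical chemical criteria.

All tables ship with documented defaults and can be overridden from a YAML
run-configuration file; :func:`default_parameters` builds the in-package
defaults and :meth:`ParameterSet.to_yaml` / :meth:`ParameterSet.from_yaml`
round-trip them bit-exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "InvalidInputError",
    "ConfigurationError",
    "GlobalConstants",
    "SoilParams",
    "VegParams",
    "EcosystemCriteria",
    "ParameterSet",
    "DRAINAGE_CLASSES",
    "FOREST_CLASSES",
    "SOIL_AGE_YEARS",
    "KGIBB_OM_EDGES",
    "KGIBB_VALUES",
    "FOREST_FDE",
    "lookup_kgibb",
    "lookup_soil_age",
    "drainage_to_fde",
    "default_parameters",
]


class InvalidInputError(ValueError):
    """A physically invalid or out-of-range input value."""


class ConfigurationError(KeyError):
    """A parameter table is missing an entry the computation needs."""


# --- fixed method tables -----------------------------------------------------

#: Gibbsite-constant ladder: organic-matter bin edges (%) and K_gibb (m6/eq2).
#: Bins are half-open [lower, upper); a value exactly on an edge falls in the
#: higher-OM (lower K_gibb) bin, consistent with the "<1.5" / ">30" labels.
KGIBB_OM_EDGES: tuple[float, ...] = (1.5, 3.5, 5.0, 15.0, 30.0)
KGIBB_VALUES: tuple[float, ...] = (9500.0, 3000.0, 950.0, 300.0, 100.0, 9.5)

#: Soil ages (years) by genetic age class, used for N immobilization.
SOIL_AGE_YEARS: dict[str, float] = {
    "skeletal_primitive": 1500.0,
    "ferralisol": 130000.0,
    "other": 5000.0,
}

#: Observation-based denitrification fractions of the main forest types.
FOREST_FDE: dict[str, float] = {
    "tropical_broadleaf": 0.65,
    "temperate_coniferous": 0.20,
    "temperate_broadleaf": 0.25,
    "subtropical": 0.35,
}

FOREST_CLASSES: tuple[str, ...] = tuple(FOREST_FDE) + ("non_forest",)

#: Seven-level ordinal drainage scale (HWSD convention), driest to wettest.
DRAINAGE_CLASSES: tuple[str, ...] = (
    "excessively_drained",
    "somewhat_excessively_drained",
    "well_drained",
    "moderately_well_drained",
    "imperfectly_drained",
    "poorly_drained",
    "very_poorly_drained",
)

_FDE_DRAINAGE_MIN = 0.0
_FDE_DRAINAGE_MAX = 0.8


# --- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class GlobalConstants:
    """Global physical constants and rule thresholds of the method.

    Defaults are the method's standard conditions: Arrhenius constant
    A = 3600 K, reference soil temperature 281 K, reference specific surface
    area 1.1e6 m2/m3 and reference bulk density 1.2 g/cm3.
    """

    arrhenius_A: float = 3600.0          # K
    T_ref: float = 281.0                 # K
    ssa_ref: float = 1.1                 # 1e6 m2/m3
    rho_ref: float = 1.2                 # g/cm3
    caco3_threshold: float = 0.5         # mass %, strict ">" for carbonate path
    caco3_slope: float = 0.82            # keq/ha/yr per % CaCO3
    fde_coarse_value: float = 0.1        # override for coarse soils
    ssa_coarse_threshold: float = 2.0    # 1e6 m2/m3
    csw_min: float = 0.7
    csw_max: float = 1.3
    #: g per charge equivalent; N fixed at 14.0 so Q[m/yr] x 1.4 mg N/L is
    #: exactly 1 keq/ha/yr.
    equivalent_weights: dict[str, float] = field(
        default_factory=lambda: {"N": 14.0, "Ca": 20.0, "Mg": 12.15, "K": 39.1}
    )
    #: molar shares combining Ca/Mg/K into one aggregate Bc equivalent weight
    bc_molar_shares: dict[str, float] = field(
        default_factory=lambda: {"Ca": 0.60, "Mg": 0.25, "K": 0.15}
    )

    @property
    def bc_equivalent_weight(self) -> float:
        """Aggregate g/eq of the Ca+Mg+K mixture: total mass / total charge."""
        charge = {"Ca": 2.0, "Mg": 2.0, "K": 1.0}
        mass = sum(
            n * charge[k] * self.equivalent_weights[k]
            for k, n in self.bc_molar_shares.items()
        )
        eq = sum(n * charge[k] for k, n in self.bc_molar_shares.items())
        return mass / eq


@dataclass(frozen=True)
class SoilParams:
    """Per-soil-type parameters: baseline weathering and genetic age class."""

    soil_type_id: int
    bcw0: float                  # keq/ha/yr at standard conditions
    soil_age_class: str          # key of SOIL_AGE_YEARS

    def __post_init__(self) -> None:
        if self.bcw0 < 0:
            raise InvalidInputError(f"bcw0 must be >= 0, got {self.bcw0}")
        if self.soil_age_class not in SOIL_AGE_YEARS:
            raise InvalidInputError(
                f"unknown soil age class {self.soil_age_class!r}"
            )


@dataclass(frozen=True)
class VegParams:
    """Per-vegetation-type biomass removal parameters and mask flag."""

    veg_type_id: int
    forest_class: str            # one of FOREST_CLASSES
    p_harvest: float             # biomass fraction in the removable part
    c_n: float                   # N mass fraction of removable biomass
    c_bc: float                  # Bc (Ca+Mg+K) mass fraction
    is_cropland_or_bare: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_harvest <= 1.0:
            raise InvalidInputError(f"p_harvest out of [0,1]: {self.p_harvest}")
        if self.c_n < 0 or self.c_bc < 0:
            raise InvalidInputError("element contents must be >= 0")
        if self.forest_class not in FOREST_CLASSES:
            raise InvalidInputError(f"unknown forest class {self.forest_class!r}")


@dataclass(frozen=True)
class EcosystemCriteria:
    """Critical chemical criteria per ecosystem type."""

    veg_type_id: int
    bcal_crit: float             # critical molar Bc:Al ratio
    n_conc_crit: float           # mg N/L in runoff

    def __post_init__(self) -> None:
        if not self.bcal_crit > 0:
            raise InvalidInputError(f"bcal_crit must be > 0: {self.bcal_crit}")
        if self.n_conc_crit < 0:
            raise InvalidInputError("n_conc_crit must be >= 0")


# --- lookup operations -------------------------------------------------------


def lookup_kgibb(om_percent):
    """Gibbsite equilibrium constant (m6/eq2) from soil organic matter (%).

    Piecewise constant and non-increasing over the six OM bins; accepts
    scalars or arrays. Raises on negative or non-finite input.
    """
    om = np.asarray(om_percent, dtype=np.float64)
    if np.any(~np.isfinite(om)) or np.any(om < 0):
        raise InvalidInputError("organic matter % must be finite and >= 0")
    idx = np.searchsorted(np.asarray(KGIBB_OM_EDGES), om, side="right")
    out = np.asarray(KGIBB_VALUES)[idx]
    return float(out) if np.isscalar(om_percent) else out


def lookup_soil_age(soil_age_class: str) -> float:
    """Soil age in years for one of the three genetic age classes."""
    try:
        return SOIL_AGE_YEARS[soil_age_class]
    except KeyError:
        raise InvalidInputError(
            f"unknown soil age class {soil_age_class!r}; "
            f"expected one of {sorted(SOIL_AGE_YEARS)}"
        ) from None


def drainage_to_fde(drainage) -> float:
    """Denitrification fraction from the 7-level drainage scale.

    Linear from 0.0 (excessively drained) to 0.8 (very poorly drained).
    Accepts a class name or a 1-based ordinal level (1..7).
    """
    if isinstance(drainage, str):
        try:
            i = DRAINAGE_CLASSES.index(drainage)
        except ValueError:
            raise InvalidInputError(
                f"unknown drainage class {drainage!r}"
            ) from None
    else:
        level = int(drainage)
        if not 1 <= level <= len(DRAINAGE_CLASSES):
            raise InvalidInputError(f"drainage level out of 1..7: {drainage}")
        i = level - 1
    n = len(DRAINAGE_CLASSES) - 1
    return _FDE_DRAINAGE_MIN + (_FDE_DRAINAGE_MAX - _FDE_DRAINAGE_MIN) * (i / n)


# --- parameter set + config round-trip ---------------------------------------


@dataclass
class ParameterSet:
    """The full resolvable parameter state of one run."""

    constants: GlobalConstants
    soils: dict[int, SoilParams]
    vegetation: dict[int, VegParams]
    criteria: dict[int, EcosystemCriteria]

    def soil(self, soil_type_id: int) -> SoilParams:
        try:
            return self.soils[int(soil_type_id)]
        except KeyError:
            raise ConfigurationError(
                f"no soil parameters for soil type {soil_type_id}"
            ) from None

    def veg(self, veg_type_id: int) -> VegParams:
        try:
            return self.vegetation[int(veg_type_id)]
        except KeyError:
            raise ConfigurationError(
                f"no vegetation parameters for type {veg_type_id}"
            ) from None

    def criterion(self, veg_type_id: int) -> EcosystemCriteria:
        try:
            return self.criteria[int(veg_type_id)]
        except KeyError:
            raise ConfigurationError(
                f"no chemical criteria for ecosystem type {veg_type_id}"
            ) from None

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "constants": dataclasses.asdict(self.constants),
            "soils": [dataclasses.asdict(s) for s in self.soils.values()],
            "vegetation": [dataclasses.asdict(v) for v in self.vegetation.values()],
            "criteria": [dataclasses.asdict(c) for c in self.criteria.values()],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls(
            constants=GlobalConstants(**d["constants"]),
            soils={s["soil_type_id"]: SoilParams(**s) for s in d["soils"]},
            vegetation={v["veg_type_id"]: VegParams(**v) for v in d["vegetation"]},
            criteria={c["veg_type_id"]: EcosystemCriteria(**c) for c in d["criteria"]},
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ParameterSet":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)


def default_parameters() -> ParameterSet:
    """The in-package default parameter tables.

    Baseline weathering rates, critical Bc/Al ratios, critical N
    concentrations and biomass parameters are implementer-chosen placeholder
    defaults spanning the ranges typical of the critical-load literature;
    real applications override them from a run config.
    """
    soils = {
        1: SoilParams(1, bcw0=0.20, soil_age_class="skeletal_primitive"),
        2: SoilParams(2, bcw0=0.50, soil_age_class="other"),
        3: SoilParams(3, bcw0=0.35, soil_age_class="ferralisol"),
        4: SoilParams(4, bcw0=1.00, soil_age_class="other"),
        5: SoilParams(5, bcw0=1.60, soil_age_class="other"),
        6: SoilParams(6, bcw0=0.80, soil_age_class="ferralisol"),
    }
    # veg ids: 1-4 the four forest classes, 5 grassland, 6 shrub,
    # 7 cropland and 8 bare ground (both masked)
    vegetation = {
        1: VegParams(1, "tropical_broadleaf", 0.30, 0.0050, 0.0040),
        2: VegParams(2, "temperate_coniferous", 0.35, 0.0030, 0.0025),
        3: VegParams(3, "temperate_broadleaf", 0.30, 0.0050, 0.0040),
        4: VegParams(4, "subtropical", 0.30, 0.0045, 0.0035),
        5: VegParams(5, "non_forest", 0.50, 0.0150, 0.0050),   # grassland tops
        6: VegParams(6, "non_forest", 0.20, 0.0080, 0.0045),   # shrub branches
        7: VegParams(7, "non_forest", 0.0, 0.0, 0.0, is_cropland_or_bare=True),
        8: VegParams(8, "non_forest", 0.0, 0.0, 0.0, is_cropland_or_bare=True),
    }
    criteria = {
        1: EcosystemCriteria(1, bcal_crit=0.8, n_conc_crit=0.4),
        2: EcosystemCriteria(2, bcal_crit=1.0, n_conc_crit=0.2),
        3: EcosystemCriteria(3, bcal_crit=0.8, n_conc_crit=0.4),
        4: EcosystemCriteria(4, bcal_crit=1.0, n_conc_crit=0.4),
        5: EcosystemCriteria(5, bcal_crit=0.8, n_conc_crit=0.3),
        6: EcosystemCriteria(6, bcal_crit=1.0, n_conc_crit=0.3),
        7: EcosystemCriteria(7, bcal_crit=1.0, n_conc_crit=0.3),
        8: EcosystemCriteria(8, bcal_crit=1.0, n_conc_crit=0.3),
    }
    return ParameterSet(GlobalConstants(), soils, vegetation, criteria)
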