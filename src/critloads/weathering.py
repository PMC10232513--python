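"""Effective base-cation weathering flux Bc_w per cell.

Baseline weathering rates (per soil type, at the standard conditions
T = 281 K, bulk density 1.2 g/cm3, SSA 1.1e6 m2/m3) are corrected for soil
moisture, specific surface area and temperature:

    Bc_w1 = C_sw * SSA / (1.1 * 1.2) * exp(A/T - A/281) * Bc_w0

with SSA estimated from texture, gravel and bulk density:

    SSA = (0.3 X_sand + 2.2 X_silt + 8.0 f_clay X_clay) * (1 - S) * rho_soil
    f_clay = 1 - X_clay^2.5 / (X_clay^2.5 + 0.35)

Calcareous soils short-circuit the silicate correction entirely: when CaCO3
content exceeds 0.5 mass % the weathering rate is CaCO3(%) * 0.82 keq/ha/yr,
replacing (not adding to) the silicate rate; below the threshold the
carbonate is assumed depletable under long-term acid input and is ignored.

All numeric operations accept scalars or numpy arrays and broadcast, so the
gridded pipeline and the scalar per-cell path share the same code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import GlobalConstants, InvalidInputError

__all__ = [
    "TextureProfile",
    "MoistureState",
    "clay_factor",
    "specific_surface_area",
    "moisture_factor",
    "temperature_factor",
    "silicate_weathering",
    "carbonate_weathering",
    "effective_weathering",
]

_TEXTURE_TOL = 0.02  # re-normalize fractions within 2% of unity, else invalid


@dataclass(frozen=True)
class TextureProfile:
    """Mineral texture of the homogenized soil layer of one cell.

    ``x_sand + x_silt + x_clay`` must equal 1 within 2%; fractions are
    re-normalized to exactly 1 on construction. ``gravel`` is the
    coarse-fragment fraction S; ``rho_soil`` the bulk density in g/cm3.
    """

    x_sand: float
    x_silt: float
    x_clay: float
    gravel: float = 0.0
    rho_soil: float = 1.2

    def __post_init__(self) -> None:
        total = self.x_sand + self.x_silt + self.x_clay
        if not np.isfinite(total) or abs(total - 1.0) > _TEXTURE_TOL:
            raise InvalidInputError(
                f"texture fractions sum to {total}, not 1 within {_TEXTURE_TOL}"
            )
        for name in ("x_sand", "x_silt", "x_clay", "gravel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name}={v} out of [0, 1]")
        if not self.rho_soil > 0:
            raise InvalidInputError(f"rho_soil must be > 0: {self.rho_soil}")
        if total != 1.0:
            object.__setattr__(self, "x_sand", self.x_sand / total)
            object.__setattr__(self, "x_silt", self.x_silt / total)
            object.__setattr__(self, "x_clay", self.x_clay / total)


@dataclass(frozen=True)
class MoistureState:
    """Volumetric soil moisture with its wilting / holding-capacity bounds."""

    theta: float
    theta_wilt: float
    theta_hold: float

    def __post_init__(self) -> None:
        if not self.theta_wilt < self.theta_hold:
            raise InvalidInputError(
                f"theta_wilt ({self.theta_wilt}) must be < theta_hold "
                f"({self.theta_hold})"
            )
        if self.theta < 0 or self.theta_wilt < 0:
            raise InvalidInputError("moisture values must be >= 0")


def clay_factor(x_clay):
    """Clay correction factor f_clay = 1 - x^2.5 / (x^2.5 + 0.35).

    Strictly decreasing from 1 at x_clay = 0 to 1/1.35... at x_clay = 1.
    """
    x = np.asarray(x_clay, dtype=np.float64)
    if np.any(x < 0) or np.any(x > 1):
        raise InvalidInputError("clay fraction out of [0, 1]")
    p = x**2.5
    out = 1.0 - p / (p + 0.35)
    return float(out) if np.isscalar(x_clay) else out


def specific_surface_area(texture: TextureProfile) -> float:
    """Specific surface area in 1e6 m2/m3 from texture, gravel and density."""
    return ssa_from_fields(
        texture.x_sand, texture.x_silt, texture.x_clay,
        texture.gravel, texture.rho_soil,
    )


def ssa_from_fields(x_sand, x_silt, x_clay, gravel, rho_soil):
    """Vectorized SSA: (0.3 sand + 2.2 silt + 8.0 f_clay clay)(1 - S) rho."""
    fine = 0.3 * np.asarray(x_sand) + 2.2 * np.asarray(x_silt) \
        + 8.0 * clay_factor(x_clay) * np.asarray(x_clay)
    out = fine * (1.0 - np.asarray(gravel)) * np.asarray(rho_soil)
    return float(out) if np.isscalar(x_sand) else out


def moisture_factor(m: MoistureState, constants: GlobalConstants | None = None):
    """Soil-moisture correction C_sw in [0.7, 1.3].

    0.7 below the wilting point, 1.3 above water holding capacity, linear
    in between.
    """
    c = constants or GlobalConstants()
    return csw_from_fields(m.theta, m.theta_wilt, m.theta_hold, c)


def csw_from_fields(theta, theta_wilt, theta_hold,
                    constants: GlobalConstants | None = None):
    c = constants or GlobalConstants()
    tw = np.asarray(theta_wilt, dtype=np.float64)
    th = np.asarray(theta_hold, dtype=np.float64)
    if np.any(tw >= th):
        raise InvalidInputError("theta_wilt must be < theta_hold")
    t = np.asarray(theta, dtype=np.float64)
    frac = (t - tw) / (th - tw)
    out = np.clip(c.csw_min + (c.csw_max - c.csw_min) * frac,
                  c.csw_min, c.csw_max)
    return float(out) if np.isscalar(theta) else out


def temperature_factor(T, constants: GlobalConstants | None = None):
    """Temperature correction exp(A/T - A/281), 1 at the 281 K reference.

    As printed the factor decreases with temperature (the exponent A/T - A/281
    falls as T rises); colder soils get factors above 1.
    """
    c = constants or GlobalConstants()
    t = np.asarray(T, dtype=np.float64)
    if np.any(t <= 0):
        raise InvalidInputError("soil temperature must be > 0 K")
    out = np.exp(c.arrhenius_A / t - c.arrhenius_A / c.T_ref)
    return float(out) if np.isscalar(T) else out


def silicate_weathering(bcw0, texture: TextureProfile, m: MoistureState, T,
                        constants: GlobalConstants | None = None) -> float:
    """Corrected silicate weathering Bc_w1 (keq/ha/yr), linear in bcw0."""
    c = constants or GlobalConstants()
    if np.any(np.asarray(bcw0) < 0):
        raise InvalidInputError("bcw0 must be >= 0")
    ssa = specific_surface_area(texture)
    return (
        moisture_factor(m, c)
        * ssa / (c.ssa_ref * c.rho_ref)
        * temperature_factor(T, c)
        * bcw0
    )


def carbonate_weathering(caco3_percent,
                         constants: GlobalConstants | None = None):
    """Carbonate weathering rate, or None when the pathway does not apply.

    Applies only when CaCO3 content strictly exceeds the 0.5 % threshold;
    then the rate is content (%) times 0.82 keq/ha/yr.
    """
    c = constants or GlobalConstants()
    if caco3_percent < 0:
        raise InvalidInputError("CaCO3 content must be >= 0")
    if caco3_percent > c.caco3_threshold:
        return caco3_percent * c.caco3_slope
    return None


def effective_weathering(bcw0, texture: TextureProfile, m: MoistureState, T,
                         caco3_percent,
                         constants: GlobalConstants | None = None,
                         ) -> tuple[float, str]:
    """Effective Bc_w for one cell and which pathway produced it.

    Returns ``(flux keq/ha/yr, pathway)`` with pathway ``"carbonate"`` or
    ``"silicate"``. The carbonate rate, when applicable, replaces the
    corrected silicate rate entirely.
    """
    c = constants or GlobalConstants()
    carb = carbonate_weathering(caco3_percent, c)
    if carb is not None:
        return carb, "carbonate"
    return silicate_weathering(bcw0, texture, m, T, c), "silicate"
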