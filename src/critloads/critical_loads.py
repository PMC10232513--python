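"""Assembly of the four critical loads per cell.

    CL_max(S)  = Bc_dep + Bc_w - Bc_u - ANC_le,crit
    CL_min(N)  = N_u + N_i
    CL_max(N)  = CL_min(N) + CL_max(S) / (1 - f_de)
    CL_nut(N)  = CL_min(N) + N_le,crit / (1 - f_de)

plus the cropland / no-vegetation mask (critical loads cannot be defined
there) and per-cell audit flags. ``compute_cell`` chains the full method —
weathering, biotic fluxes, chemistry, assembly — for a single CellRecord;
the gridded pipeline applies the identical arithmetic vectorized.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import biotic_fluxes as bf
from . import critical_chemistry as chem
from . import weathering as wx
from .parameters import InvalidInputError, ParameterSet, lookup_kgibb

__all__ = [
    "CellFlag",
    "CellRecord",
    "FluxSet",
    "CriticalLoads",
    "NODATA",
    "cl_max_s",
    "cl_min_n",
    "cl_max_n",
    "cl_nut_n",
    "compute_fluxes",
    "assemble_loads",
    "compute_cell",
]

NODATA = -9999.0


class CellFlag(enum.IntFlag):
    """Audit flags, emitted as a bitmask layer alongside the outputs."""

    NONE = 0
    CARBONATE = 1     # carbonate weathering pathway used
    CLAMPED = 2       # bc_net clamped at zero (uptake exceeded supply)
    MASKED = 4        # cropland / no vegetation: loads undefined
    COARSE_FDE = 8    # coarse-soil denitrification override applied


@dataclass(frozen=True)
class CellRecord:
    """All per-cell physical inputs of one grid cell."""

    soil_type: int
    veg_type: int
    drainage: int              # ordinal 1..7, dry to wet
    texture: wx.TextureProfile
    moisture: wx.MoistureState
    soil_temperature: float    # K
    om_percent: float          # soil organic matter, mass %
    caco3_percent: float       # mass %
    n_areal: float             # soil N pool, kg N/m2
    npp: float                 # g dry matter/m2/yr
    runoff: float              # m/yr
    bc_dep: float              # keq/ha/yr, Ca+Mg+K charge equivalents


@dataclass
class FluxSet:
    """Intermediate per-cell fluxes feeding the four load equations."""

    bc_dep: float
    bc_w: float
    bc_u: float
    n_u: float
    n_i: float
    f_de: float
    anc_le_crit: float
    n_le_crit: float
    flags: CellFlag = CellFlag.NONE
    #: net base-cation supply after the clamp at zero; derived when omitted
    bc_net: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_de < 1.0:
            raise InvalidInputError(f"f_de out of [0, 1): {self.f_de}")
        if self.anc_le_crit > 0:
            raise InvalidInputError("anc_le_crit must be <= 0")
        if self.bc_net is None:
            net = self.bc_dep + self.bc_w - self.bc_u
            self.bc_net = net if net >= 0.0 else 0.0


@dataclass
class CriticalLoads:
    """The four critical loads of one cell (keq/ha/yr) with audit flags."""

    cl_max_s: float
    cl_min_n: float
    cl_max_n: float
    cl_nut_n: float
    flags: CellFlag = CellFlag.NONE

    @property
    def is_masked(self) -> bool:
        return bool(self.flags & CellFlag.MASKED)


# --- the four load equations (scalar or array) -------------------------------


def cl_max_s(f: FluxSet) -> float:
    """CL_max(S) = Bc_dep + Bc_w - Bc_u - ANC_le,crit.

    The net base-cation term is the clamped ``bc_net`` (cells where uptake
    exceeds supply contribute zero, keeping CL_max(S) >= 0); for unclamped
    cells this is exactly the printed sum.
    """
    return f.bc_net - f.anc_le_crit


def cl_min_n(f: FluxSet) -> float:
    """CL_min(N) = N_u + N_i."""
    return f.n_u + f.n_i


def cl_max_n(f: FluxSet, clmaxs: float) -> float:
    """CL_max(N) = CL_min(N) + CL_max(S) / (1 - f_de)."""
    if f.f_de >= 1.0:
        raise InvalidInputError("f_de must be < 1")
    return cl_min_n(f) + clmaxs / (1.0 - f.f_de)


def cl_nut_n(f: FluxSet) -> float:
    """CL_nut(N) = CL_min(N) + N_le,crit / (1 - f_de)."""
    if f.f_de >= 1.0:
        raise InvalidInputError("f_de must be < 1")
    return cl_min_n(f) + f.n_le_crit / (1.0 - f.f_de)


# --- per-cell pipeline -------------------------------------------------------


def compute_fluxes(cell: CellRecord, params: ParameterSet) -> FluxSet:
    """Run weathering, biotic fluxes and chemistry for one unmasked cell."""
    c = params.constants
    soil = params.soil(cell.soil_type)
    veg = params.veg(cell.veg_type)
    crit = params.criterion(cell.veg_type)
    flags = CellFlag.NONE

    bc_w, pathway = wx.effective_weathering(
        soil.bcw0, cell.texture, cell.moisture, cell.soil_temperature,
        cell.caco3_percent, c,
    )
    if pathway == "carbonate":
        flags |= CellFlag.CARBONATE

    uptake = bf.UptakeInputs(cell.npp, veg)
    n_u = bf.net_uptake(uptake, "N", c)
    bc_u = bf.net_uptake(uptake, "Bc", c)
    pool = bf.NitrogenPool.from_age_class(cell.n_areal, soil.soil_age_class)
    n_i = bf.n_immobilization(pool, c)

    ssa = wx.specific_surface_area(cell.texture)
    f_de, coarse = bf.denitrification_fraction(veg, cell.drainage, ssa, c)
    if coarse:
        flags |= CellFlag.COARSE_FDE

    bc_net = cell.bc_dep + bc_w - bc_u
    if bc_net < 0.0:
        bc_net = 0.0
        flags |= CellFlag.CLAMPED

    kgibb = lookup_kgibb(cell.om_percent)
    anc = chem.anc_leaching_critical(
        chem.ChemistryInputs(cell.runoff, bc_net, kgibb, crit.bcal_crit)
    )
    n_le = chem.n_leaching_critical(cell.runoff, crit.n_conc_crit)

    return FluxSet(
        bc_dep=cell.bc_dep, bc_w=bc_w, bc_u=bc_u, n_u=n_u, n_i=n_i,
        f_de=f_de, anc_le_crit=anc, n_le_crit=n_le, flags=flags,
        bc_net=bc_net,
    )


def assemble_loads(f: FluxSet) -> CriticalLoads:
    """Evaluate the four load equations from a FluxSet."""
    s = cl_max_s(f)
    return CriticalLoads(
        cl_max_s=s,
        cl_min_n=cl_min_n(f),
        cl_max_n=cl_max_n(f, s),
        cl_nut_n=cl_nut_n(f),
        flags=f.flags,
    )


def compute_cell(cell: CellRecord, params: ParameterSet) -> CriticalLoads:
    """Full per-cell computation, including the cropland/no-vegetation mask.

    Cropland and unvegetated cells return NODATA in all four loads with the
    MASKED flag — critical loads are undefined there by construction.
    """
    veg = params.veg(cell.veg_type)
    if veg.is_cropland_or_bare:
        return CriticalLoads(NODATA, NODATA, NODATA, NODATA, CellFlag.MASKED)
    return assemble_loads(compute_fluxes(cell, params))
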