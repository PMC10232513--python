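"""Gridded execution: layer stacks, TIFF I/O, and the vectorized pipeline.

A :class:`LayerStack` holds named single-band rasters sharing one grid
geometry (affine transform + CRS tag, pixel-is-area, row-major from the
top-left corner). On disk each layer is a single-band TIFF whose
ImageDescription tag carries a JSON document with the transform, CRS, nodata
value and units tag; arrays are float64 in memory and float32 on disk.

``run_pipeline`` executes the whole critical-load method over the grid with
numpy array arithmetic that reuses the very same elementwise routines as the
scalar per-cell path, so the two are equivalent cell by cell.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import biotic_fluxes as bf
from . import critical_chemistry as chem
from . import weathering as wx
from .critical_loads import NODATA, CellFlag, CellRecord
from .parameters import (
    FOREST_FDE,
    ConfigurationError,
    InvalidInputError,
    ParameterSet,
    lookup_kgibb,
)

__all__ = [
    "LayerStack",
    "REQUIRED_LAYERS",
    "GeometryError",
    "PipelineError",
    "load_stack",
    "write_stack",
    "run_pipeline",
    "cell_from_stack",
]

#: layer name -> units tag expected by the pipeline
REQUIRED_LAYERS: dict[str, str] = {
    "soil_type": "class",
    "veg_type": "class",
    "drainage": "class 1-7",
    "x_sand": "fraction",
    "x_silt": "fraction",
    "x_clay": "fraction",
    "gravel": "fraction",
    "rho_soil": "g/cm3",
    "om_percent": "%",
    "caco3_percent": "%",
    "n_areal": "kg N/m2",
    "soil_temperature": "K",
    "theta": "m3/m3",
    "theta_wilt": "m3/m3",
    "theta_hold": "m3/m3",
    "npp": "g DM/m2/yr",
    "runoff": "m/yr",
    "bc_dep": "keq/ha/yr",
}

OUTPUT_LAYERS = ("clmaxs", "clminn", "clmaxn", "clnutn")


class GeometryError(ValueError):
    """Layers do not share one grid geometry."""


class PipelineError(RuntimeError):
    """A stage failed at specific cells."""


@dataclass
class LayerStack:
    """Co-registered named rasters on one grid."""

    layers: dict[str, np.ndarray]
    transform: tuple[float, float, float, float, float, float] = (
        1.0, 0.0, 0.0, 0.0, -1.0, 0.0,
    )
    crs: str = "local"
    nodata: float = NODATA
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {name: a.shape for name, a in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise GeometryError(f"layer shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def validate(self, required=REQUIRED_LAYERS) -> None:
        missing = sorted(set(required) - set(self.layers))
        if missing:
            raise ConfigurationError(f"missing required layers: {missing}")

    def checksum(self) -> str:
        """SHA-256 over layer names, geometry and float64 cell values."""
        h = hashlib.sha256()
        h.update(repr(self.transform).encode())
        for name in sorted(self.layers):
            h.update(name.encode())
            h.update(np.ascontiguousarray(
                self.layers[name], dtype=np.float64).tobytes())
        return h.hexdigest()


def write_stack(stack: LayerStack, directory, dtype=np.float32) -> list[Path]:
    """One single-band TIFF per layer; geometry/nodata/units as JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in stack.layers.items():
        meta = {
            "transform": list(stack.transform),
            "crs": stack.crs,
            "nodata": stack.nodata,
            "units": stack.units.get(name, ""),
        }
        path = directory / f"{name}.tif"
        tifffile.imwrite(path, np.asarray(arr, dtype=dtype),
                         description=json.dumps(meta))
        paths.append(path)
    return paths


def load_stack(source, required=None) -> LayerStack:
    """Read a stack from a directory of TIFFs (or a name->path mapping).

    All layers must share the same shape and affine transform; mismatches
    raise :class:`GeometryError` listing the offending layers.
    """
    if isinstance(source, (str, Path)):
        paths = {p.stem: p for p in sorted(Path(source).glob("*.tif"))}
    else:
        paths = {k: Path(v) for k, v in source.items()}
    if not paths:
        raise ConfigurationError(f"no raster layers found in {source}")
    layers, metas = {}, {}
    for name, path in paths.items():
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            if arr.ndim != 2:
                raise ConfigurationError(f"{name}: not a single-band raster")
            desc = page.tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        layers[name] = np.asarray(arr, dtype=np.float64)
        metas[name] = meta
    ref_name = next(iter(metas))
    ref_t = tuple(metas[ref_name].get("transform", (1, 0, 0, 0, -1, 0)))
    ref_shape = layers[ref_name].shape
    bad = [
        n for n in layers
        if tuple(metas[n].get("transform", ref_t)) != ref_t
        or layers[n].shape != ref_shape
    ]
    if bad:
        raise GeometryError(
            f"layers not co-registered with {ref_name!r}: {sorted(bad)}"
        )
    stack = LayerStack(
        layers=layers,
        transform=ref_t,
        crs=metas[ref_name].get("crs", "local"),
        nodata=float(metas[ref_name].get("nodata", NODATA)),
        units={n: m.get("units", "") for n, m in metas.items()},
    )
    if required is not None:
        stack.validate(required)
    return stack


def cell_from_stack(stack: LayerStack, row: int, col: int) -> CellRecord:
    """Assemble the scalar CellRecord of one grid cell (for the scalar path)."""
    g = {name: float(stack[name][row, col]) for name in REQUIRED_LAYERS}
    return CellRecord(
        soil_type=int(g["soil_type"]),
        veg_type=int(g["veg_type"]),
        drainage=int(g["drainage"]),
        texture=wx.TextureProfile(
            g["x_sand"], g["x_silt"], g["x_clay"], g["gravel"], g["rho_soil"]
        ),
        moisture=wx.MoistureState(g["theta"], g["theta_wilt"], g["theta_hold"]),
        soil_temperature=g["soil_temperature"],
        om_percent=g["om_percent"],
        caco3_percent=g["caco3_percent"],
        n_areal=g["n_areal"],
        npp=g["npp"],
        runoff=g["runoff"],
        bc_dep=g["bc_dep"],
    )


def _class_lookup(ids: np.ndarray, table: dict[int, float],
                  what: str) -> np.ndarray:
    """Map an integer class raster through a {id: value} table."""
    present = set(np.unique(ids[np.isfinite(ids)]).astype(int))
    unknown = sorted(present - set(table))
    if unknown:
        raise ConfigurationError(f"no {what} for class ids {unknown}")
    lut = np.full(max(table) + 1, np.nan)
    for k, v in table.items():
        lut[k] = v
    return lut[ids.astype(np.intp)]


def run_pipeline(stack: LayerStack, params: ParameterSet,
                 ) -> tuple[LayerStack, dict]:
    """Compute the four critical-load layers plus the flag bitmask.

    Returns ``(outputs, report)``: outputs carry clmaxs/clminn/clmaxn/clnutn
    (keq/ha/yr, NODATA where masked) and an integer ``flags`` layer; the
    report counts masked/clamped/carbonate/coarse cells and gives min/median/
    max per output over valid cells. Deterministic for fixed inputs.
    """
    stack.validate()
    c = params.constants
    shape = stack.shape
    flags = np.zeros(shape, dtype=np.int32)

    input_nodata = np.zeros(shape, dtype=bool)
    for name in REQUIRED_LAYERS:
        a = stack[name]
        input_nodata |= ~np.isfinite(a) | (a == stack.nodata)

    soil = stack["soil_type"]
    veg = stack["veg_type"]
    # class rasters must be resolvable everywhere data exists
    soil_f = np.where(input_nodata, next(iter(params.soils)), soil)
    veg_f = np.where(input_nodata, next(iter(params.vegetation)), veg)

    bcw0 = _class_lookup(soil_f, {k: s.bcw0 for k, s in params.soils.items()},
                         "soil parameters")
    age = _class_lookup(
        soil_f,
        {k: bf.lookup_soil_age(s.soil_age_class)
         for k, s in params.soils.items()},
        "soil age",
    )
    p_harvest = _class_lookup(
        veg_f, {k: v.p_harvest for k, v in params.vegetation.items()},
        "vegetation parameters")
    c_n = _class_lookup(veg_f, {k: v.c_n for k, v in params.vegetation.items()},
                        "vegetation parameters")
    c_bc = _class_lookup(veg_f, {k: v.c_bc for k, v in params.vegetation.items()},
                         "vegetation parameters")
    cropbare = _class_lookup(
        veg_f,
        {k: float(v.is_cropland_or_bare) for k, v in params.vegetation.items()},
        "vegetation parameters") > 0.5
    forest_fde = _class_lookup(
        veg_f,
        {k: FOREST_FDE.get(v.forest_class, np.nan)
         for k, v in params.vegetation.items()},
        "forest class")
    bcal = _class_lookup(
        veg_f, {k: cr.bcal_crit for k, cr in params.criteria.items()},
        "chemical criteria")
    nconc = _class_lookup(
        veg_f, {k: cr.n_conc_crit for k, cr in params.criteria.items()},
        "chemical criteria")

    masked = input_nodata | cropbare
    flags[masked] |= CellFlag.MASKED

    # texture: renormalize within 2% of unity, else mask
    x_sand, x_silt, x_clay = stack["x_sand"], stack["x_silt"], stack["x_clay"]
    with np.errstate(invalid="ignore", divide="ignore"):
        total = x_sand + x_silt + x_clay
        bad_texture = ~masked & (np.abs(total - 1.0) > 0.02)
        masked |= bad_texture
        flags[bad_texture] |= CellFlag.MASKED
        safe_total = np.where(total > 0, total, 1.0)
        x_sand, x_silt, x_clay = (x_sand / safe_total, x_silt / safe_total,
                                  x_clay / safe_total)

        ssa = wx.ssa_from_fields(x_sand, x_silt, x_clay,
                                 stack["gravel"], stack["rho_soil"])

        bad_moist = ~masked & (stack["theta_wilt"] >= stack["theta_hold"])
        masked |= bad_moist
        flags[bad_moist] |= CellFlag.MASKED
        tw = np.where(stack["theta_wilt"] < stack["theta_hold"],
                      stack["theta_wilt"], 0.0)
        th = np.where(stack["theta_wilt"] < stack["theta_hold"],
                      stack["theta_hold"], 1.0)
        csw = wx.csw_from_fields(stack["theta"], tw, th, c)
        tfac = wx.temperature_factor(np.maximum(stack["soil_temperature"], 1.0), c)

        bc_w_sil = csw * (ssa / (c.ssa_ref * c.rho_ref)) * tfac * bcw0
        carbonate = stack["caco3_percent"] > c.caco3_threshold
        bc_w = np.where(carbonate, stack["caco3_percent"] * c.caco3_slope,
                        bc_w_sil)
        flags[carbonate & ~masked] |= CellFlag.CARBONATE

        npp = stack["npp"]
        n_u = bf.mass_flux_to_keq(npp * p_harvest * c_n,
                                  c.equivalent_weights["N"])
        bc_u = bf.mass_flux_to_keq(npp * p_harvest * c_bc,
                                   c.bc_equivalent_weight)
        n_i = bf.mass_flux_to_keq(stack["n_areal"] * 1000.0 / age,
                                  c.equivalent_weights["N"])

        fde_drain = 0.0 + (0.8 - 0.0) * ((stack["drainage"] - 1.0) / 6.0)
        coarse = ssa < c.ssa_coarse_threshold
        fde_nonforest = np.where(coarse, c.fde_coarse_value, fde_drain)
        is_forest = np.isfinite(forest_fde)
        f_de = np.where(is_forest, forest_fde, fde_nonforest)
        flags[~is_forest & coarse & ~masked] |= CellFlag.COARSE_FDE

        bc_net = stack["bc_dep"] + bc_w - bc_u
        clamped = bc_net < 0.0
        flags[clamped & ~masked] |= CellFlag.CLAMPED
        bc_net = np.where(clamped, 0.0, bc_net)

        kgibb = lookup_kgibb(np.maximum(stack["om_percent"], 0.0))
        anc = chem.anc_le_crit_from_fields(
            np.maximum(stack["runoff"], 0.0), bc_net, kgibb, bcal)
        n_le = np.maximum(stack["runoff"], 0.0) * nconc \
            / chem.N_EQUIVALENT_WEIGHT * chem.KEQ_PER_HA_PER_EQ_PER_M2

        clmaxs = bc_net - anc
        clminn = n_u + n_i
        clmaxn = clminn + clmaxs / (1.0 - f_de)
        clnutn = clminn + n_le / (1.0 - f_de)

    out = {}
    for name, arr in zip(OUTPUT_LAYERS, (clmaxs, clminn, clmaxn, clnutn)):
        bad = masked | ~np.isfinite(arr)
        out[name] = np.where(bad, NODATA, arr)
    out["flags"] = flags.astype(np.float64)

    valid = ~masked
    report = {
        "shape": list(shape),
        "n_cells": int(np.prod(shape)),
        "n_masked": int(masked.sum()),
        "n_clamped": int(((flags & CellFlag.CLAMPED) > 0).sum()),
        "n_carbonate": int(((flags & CellFlag.CARBONATE) > 0).sum()),
        "n_coarse_fde": int(((flags & CellFlag.COARSE_FDE) > 0).sum()),
        "params_sha256": hashlib.sha256(
            json.dumps(params.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "summary": {},
    }
    for name in OUTPUT_LAYERS:
        vals = out[name][valid]
        report["summary"][name] = (
            {"min": float(np.min(vals)), "median": float(np.median(vals)),
             "max": float(np.max(vals))}
            if vals.size else {"min": None, "median": None, "max": None}
        )

    units = {name: "keq/ha/yr" for name in OUTPUT_LAYERS}
    units["flags"] = "bitmask"
    outputs = LayerStack(out, transform=stack.transform, crs=stack.crs,
                         nodata=NODATA, units=units)
    return outputs, report
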