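"""Seeded synthetic input stacks and scalar worked fixtures.

The generator emulates the statistical structure the gridded method assumes —
spatially smooth continuous fields (low-pass-filtered Gaussian noise),
contiguous categorical patches (nearest-seed Voronoi partitions), texture
fractions on the simplex, ordered moisture triplets, zero-inflated CaCO3 —
over ranges spanning what national soil/vegetation products typically carry.
It does not emulate any real geography; it exists so every stage and the
end-to-end pipeline are testable without external downloads.

Everything is deterministic given the seed. Baseline weathering rates per
synthetic soil type are drawn once per run in 0.1-2.0 keq/ha/yr (the typical
critical-load literature range) and recorded in the generated parameter set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import weathering as wx
from .critical_loads import CellRecord
from .parameters import (
    EcosystemCriteria,
    GlobalConstants,
    InvalidInputError,
    ParameterSet,
    SoilParams,
    VegParams,
    default_parameters,
)
from .raster_pipeline import REQUIRED_LAYERS, LayerStack, write_stack

__all__ = ["SynthConfig", "generate_grid", "write_run_directory",
           "WorkedFixture", "worked_fixtures"]


@dataclass
class SynthConfig:
    """Grid size, seed, class palettes and value ranges of one synthetic run."""

    nrows: int = 50
    ncols: int = 50
    seed: int = 0
    cropland_fraction: float = 0.15
    n_soil_patches: int = 12
    n_veg_patches: int = 15
    smoothness: float = 6.0            # gaussian-filter sigma, cells
    bcw0_range: tuple = (0.1, 2.0)     # keq/ha/yr
    gravel_range: tuple = (0.0, 0.8)
    rho_range: tuple = (0.8, 1.8)      # g/cm3
    om_max: float = 40.0               # %
    caco3_max: float = 10.0            # %, zero-inflated
    n_areal_range: tuple = (0.05, 1.5)  # kg N/m2
    temp_range: tuple = (266.0, 303.0)  # K
    npp_range: tuple = (0.0, 1500.0)   # g DM/m2/yr
    runoff_range: tuple = (0.0, 1.5)   # m/yr
    bc_dep_range: tuple = (0.0, 2.0)   # keq/ha/yr

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise InvalidInputError("grid must be at least 1x1")
        if not 0.0 <= self.cropland_fraction <= 1.0:
            raise InvalidInputError("cropland_fraction out of [0, 1]")
        for name in ("bcw0_range", "gravel_range", "rho_range",
                     "n_areal_range", "temp_range", "npp_range",
                     "runoff_range", "bc_dep_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise InvalidInputError(f"invalid range {name}: {(lo, hi)}")


def _smooth_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Low-pass-filtered white noise rescaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="wrap")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


def _voronoi_classes(rng: np.random.Generator, shape, n_patches,
                     class_ids) -> np.ndarray:
    """Contiguous categorical patches: nearest of n seeded points."""
    rows = rng.uniform(0, shape[0], n_patches)
    cols = rng.uniform(0, shape[1], n_patches)
    patch_class = rng.choice(class_ids, size=n_patches)
    rr, cc = np.indices(shape)
    d2 = (rr[..., None] - rows) ** 2 + (cc[..., None] - cols) ** 2
    return patch_class[np.argmin(d2, axis=-1)].astype(np.float64)


def generate_grid(cfg: SynthConfig) -> tuple[LayerStack, ParameterSet]:
    """A complete required-layer stack plus the matching parameter set.

    The parameter set is the package default with the baseline weathering
    rates replaced by seeded draws recorded for the run.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.nrows, cfg.ncols)
    sig = cfg.smoothness

    params = default_parameters()
    soil_ids = sorted(params.soils)
    veg_ids_unmasked = [k for k, v in params.vegetation.items()
                        if not v.is_cropland_or_bare]
    bcw0_draws = rng.uniform(*cfg.bcw0_range, size=len(soil_ids))
    params = ParameterSet(
        constants=params.constants,
        soils={
            k: dataclasses.replace(params.soils[k], bcw0=float(b))
            for k, b in zip(soil_ids, bcw0_draws)
        },
        vegetation=params.vegetation,
        criteria=params.criteria,
    )

    soil = _voronoi_classes(rng, shape, cfg.n_soil_patches, soil_ids)
    veg = _voronoi_classes(rng, shape, cfg.n_veg_patches, veg_ids_unmasked)
    # cropland occupies the lowest quantile of one smooth suitability field
    crop_field = _smooth_field(rng, shape, sig)
    if cfg.cropland_fraction > 0:
        thr = np.quantile(crop_field, cfg.cropland_fraction)
        veg = np.where(crop_field <= thr, 7.0, veg)

    drainage = np.clip(
        np.floor(_smooth_field(rng, shape, sig) * 7.0) + 1.0, 1.0, 7.0)

    # texture on the simplex via softmax of three smooth fields
    logits = np.stack([_smooth_field(rng, shape, sig) * 4.0 for _ in range(3)])
    expl = np.exp(logits - logits.max(axis=0))
    frac = expl / expl.sum(axis=0)
    x_sand, x_silt, x_clay = frac

    gravel = cfg.gravel_range[0] + _smooth_field(rng, shape, sig) \
        * (cfg.gravel_range[1] - cfg.gravel_range[0])
    rho = cfg.rho_range[0] + _smooth_field(rng, shape, sig) \
        * (cfg.rho_range[1] - cfg.rho_range[0])
    om = _smooth_field(rng, shape, sig) ** 2 * cfg.om_max  # right-skewed
    cac_field = _smooth_field(rng, shape, sig)
    caco3 = np.where(cac_field > 0.7,
                     (cac_field - 0.7) / 0.3 * cfg.caco3_max, 0.0)
    n_areal = cfg.n_areal_range[0] + _smooth_field(rng, shape, sig) \
        * (cfg.n_areal_range[1] - cfg.n_areal_range[0])
    temp = cfg.temp_range[0] + _smooth_field(rng, shape, sig) \
        * (cfg.temp_range[1] - cfg.temp_range[0])

    theta_wilt = 0.05 + _smooth_field(rng, shape, sig) * 0.20
    theta_hold = theta_wilt + 0.05 + _smooth_field(rng, shape, sig) * 0.25
    theta = _smooth_field(rng, shape, sig) * 0.6

    npp = cfg.npp_range[0] + _smooth_field(rng, shape, sig) \
        * (cfg.npp_range[1] - cfg.npp_range[0])
    runoff = cfg.runoff_range[0] + _smooth_field(rng, shape, sig) \
        * (cfg.runoff_range[1] - cfg.runoff_range[0])
    bc_dep = cfg.bc_dep_range[0] + _smooth_field(rng, shape, sig) \
        * (cfg.bc_dep_range[1] - cfg.bc_dep_range[0])

    layers = {
        "soil_type": soil, "veg_type": veg, "drainage": drainage,
        "x_sand": x_sand, "x_silt": x_silt, "x_clay": x_clay,
        "gravel": gravel, "rho_soil": rho, "om_percent": om,
        "caco3_percent": caco3, "n_areal": n_areal,
        "soil_temperature": temp, "theta": theta,
        "theta_wilt": theta_wilt, "theta_hold": theta_hold,
        "npp": npp, "runoff": runoff, "bc_dep": bc_dep,
    }
    stack = LayerStack(
        layers=layers,
        transform=(1000.0, 0.0, 0.0, 0.0, -1000.0, 0.0),  # 1 km cells
        crs="synthetic-local",
        units=dict(REQUIRED_LAYERS),
    )
    return stack, params


def write_run_directory(cfg: SynthConfig, directory) -> Path:
    """Write a ready-to-run input directory: TIFF stack, params, manifest."""
    directory = Path(directory)
    stack, params = generate_grid(cfg)
    write_stack(stack, directory, dtype=np.float64)
    params.to_yaml(directory / "params.yaml")
    manifest = {"seed": cfg.seed, "nrows": cfg.nrows, "ncols": cfg.ncols,
                "cropland_fraction": cfg.cropland_fraction,
                "checksum": stack.checksum()}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


# --- scalar worked fixtures --------------------------------------------------


@dataclass(frozen=True)
class WorkedFixture:
    """A named scalar cell with its parameter set and expected outputs."""

    name: str
    cell: CellRecord
    params: ParameterSet
    expected: dict


def _fixture_params() -> ParameterSet:
    """Parameter tables of the worked scalar fixtures.

    The subtropical-forest Bc content is derived so the fixture's Bc uptake
    is exactly 0.05 keq/ha/yr at NPP 700 and p_harvest 0.3 under the default
    aggregate Bc equivalent weight.
    """
    consts = GlobalConstants()
    c_bc_a = 0.05 * consts.bc_equivalent_weight / (700.0 * 0.3 * 10.0)
    soils = {
        1: SoilParams(1, bcw0=0.35, soil_age_class="ferralisol"),
        2: SoilParams(2, bcw0=0.50, soil_age_class="other"),
    }
    vegetation = {
        1: VegParams(1, "subtropical", 0.30, 0.0050, c_bc_a),
        2: VegParams(2, "non_forest", 0.50, 0.0150, 0.0050),
        3: VegParams(3, "non_forest", 0.0, 0.0, 0.0, is_cropland_or_bare=True),
    }
    criteria = {
        1: EcosystemCriteria(1, bcal_crit=1.0, n_conc_crit=0.4),
        2: EcosystemCriteria(2, bcal_crit=0.8, n_conc_crit=0.3),
        3: EcosystemCriteria(3, bcal_crit=1.0, n_conc_crit=0.3),
    }
    return ParameterSet(consts, soils, vegetation, criteria)


def worked_fixtures() -> dict[str, WorkedFixture]:
    """The named scalar cells used as end-to-end worked examples.

    * ``cellA`` — non-calcareous subtropical forest cell at standard
      weathering conditions; expected loads (1.532, 0.755, 3.112, 0.887)
      keq/ha/yr.
    * ``calcareous`` — 1.0 % CaCO3 cell; carbonate pathway, Bc_w = 0.82.
    * ``cropland`` — masked, all outputs nodata.
    * ``coarse_poorly_drained`` — non-forest, very poorly drained but
      coarse soil (SSA < 2e6 m2/m3): f_de overridden to 0.1.
    """
    params = _fixture_params()
    # SSA = 2.2 * 1.2 * (1 - 0.5) = 1.32e6 m2/m3, the reference value
    texture_ref = wx.TextureProfile(0.0, 1.0, 0.0, gravel=0.5, rho_soil=1.2)
    moisture_mid = wx.MoistureState(0.2, 0.1, 0.3)  # midpoint: C_sw = 1

    cell_a = CellRecord(
        soil_type=1, veg_type=1, drainage=4, texture=texture_ref,
        moisture=moisture_mid, soil_temperature=281.0, om_percent=10.0,
        caco3_percent=0.0, n_areal=0.91, npp=700.0, runoff=0.3, bc_dep=0.2,
    )
    calcareous = dataclasses.replace(cell_a, caco3_percent=1.0)
    cropland = dataclasses.replace(cell_a, veg_type=3)
    coarse = dataclasses.replace(cell_a, veg_type=2, drainage=7)

    return {
        "cellA": WorkedFixture(
            "cellA", cell_a, params,
            expected={"cl_max_s": 1.532, "cl_min_n": 0.755,
                      "cl_max_n": 3.112, "cl_nut_n": 0.887, "rtol": 0.01},
        ),
        "calcareous": WorkedFixture(
            "calcareous", calcareous, params,
            expected={"bc_w": 0.82, "pathway": "carbonate"},
        ),
        "cropland": WorkedFixture(
            "cropland", cropland, params, expected={"masked": True},
        ),
        "coarse_poorly_drained": WorkedFixture(
            "coarse_poorly_drained", coarse, params,
            expected={"f_de": 0.1, "coarse_override": True},
        ),
    }
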