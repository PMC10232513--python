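# Methods

## Model and assumptions

`critloads` implements the steady-state mass-balance (SMB) model for soil
critical loads of sulfur and nitrogen. The model equates long-term acid
inputs with long-term sinks — base-cation weathering and deposition, net
growth uptake, nitrogen immobilization, denitrification — plus an
*acceptable* leaching term fixed by a chemical criterion. It assumes one
homogenized soil layer per cell, steady state (no dynamic soil chemistry),
and complete retention of deposited N up to CL_min(N). Sodium is excluded
from the base-cation sum because plants do not take it up.

Each cell is computed independently; there is no lateral transport. The four
outputs (CL_max(S), CL_min(N), CL_max(N), CL_nut(N)) are reported
separately; no minimum of CL_nut(N) and CL_max(N) is taken, mirroring how
such datasets are published as four independent layers.

## Weathering

Baseline weathering rates `bcw0` are a per-soil-type input (normally derived
externally with a geochemical model such as PROFILE at the standard
conditions T = 281 K, ρ = 1.2 g cm⁻³, SSA = 1.1×10⁶ m² m⁻³); deriving them
from mineralogy is out of scope. Corrections:

- moisture: C_sw = 0.7 below wilting moisture, 1.3 above water-holding
  moisture, linear between (boundary values are attained at the bounds);
- surface area: SSA = (0.3·sand + 2.2·silt + 8.0·f_clay·clay)(1 − gravel)ρ,
  f_clay = 1 − clay²·⁵/(clay²·⁵ + 0.35), carried in 10⁶ m² m⁻³ with ρ in
  g cm⁻³ so the printed normalization SSA/(1.1×1.2) applies literally. That
  normalization divides by the reference density even though SSA already
  contains ρ; the formula is implemented verbatim and the dimensional
  oddity documented here rather than resolved.
- temperature: exp(3600/T − 3600/281). As printed this factor *decreases*
  with temperature (warmer soils weather less); the implementation and its
  monotonicity tests follow the printed form, verified against a brute-force
  evaluation grid.

Calcareous soils: when CaCO₃ content strictly exceeds 0.5 % (mass), the
weathering rate is CaCO₃(%) × 0.82 keq ha⁻¹ yr⁻¹, *replacing* the corrected
silicate rate with no moisture/temperature correction; at or below 0.5 % the
carbonate is treated as depletable under long-term acid input and ignored.
Exactly 0.5 % takes the silicate pathway ("higher than" read strictly).
Carbonate cells are flagged.

Texture fractions are renormalized to sum to one when within 2 % of unity;
worse violations mask the cell with a flag.

## Biotic fluxes

Net uptake is NPP × p_harvest × element content, converted to charge
equivalents (N at 14.0 g eq⁻¹, chosen so 1 m yr⁻¹ of runoff at 1.4 mg N L⁻¹
is exactly 1 keq ha⁻¹ yr⁻¹). Base-cation contents are a single aggregate
mass fraction; the aggregate equivalent weight combines Ca 20.0, Mg 12.15
and K 39.1 g eq⁻¹ by configurable molar shares (default 0.60/0.25/0.15,
≈ 19.43 g eq⁻¹), since per-element plant contents are rarely tabulated.
Grassland above-ground removal and shrub branch removal are encoded purely
through p_harvest per vegetation class. NPP is a single long-term mean
layer; no temporal averaging happens in the pipeline.

Immobilization divides the areal soil N pool (kg N m⁻²; the integration
depth is the data product's, not the model's) by soil age: 1 500 yr for
skeletal/primitive soils, 130 000 yr for ferralisols, 5 000 yr otherwise.

Denitrification fractions: forests take observation-based values by forest
class (tropical broadleaf 0.65, temperate coniferous 0.20, temperate
broadleaf 0.25, subtropical 0.35). Other cells map the 7-level ordinal
drainage scale (HWSD convention) linearly onto [0, 0.8]; only the published
endpoints are given, so linear spacing of the intermediate classes is a
design choice. Coarse soils (SSA < 2×10⁶ m² m⁻³) are overridden to
f_de = 0.1 — only on the drainage pathway, as the forest values are
observations and need no protection against overestimation. f_de ≤ 0.8 < 1
keeps the 1/(1 − f_de) leverage finite.

## Critical chemistry

The acceptable acidity export solves two simultaneous conditions in soil
solution: the gibbsite equilibrium [Al] = K_gibb[H]³ and the critical molar
Bc:Al ratio expressed at leaching fluxes. Externally all fluxes are
keq ha⁻¹ yr⁻¹; the closed form is evaluated in eq m⁻² yr⁻¹ with Q in m yr⁻¹
and K_gibb in m⁶ eq⁻², which makes it dimensionally exact; the factor 1.5
is the equivalent-to-molar conversion (1/2)/(1/3) for divalent Bc and
trivalent Al. The second (Al) term is read as a flux term without an extra
runoff factor; this flux-based reading is the one consistent with
ANC_le = −Q([H]+[Al]), and is enforced by an independent bisection oracle
(`critical_point_oracle`) that solves for the concentrations directly and
must agree with the closed form to 1e−9 relative. Q = 0 is handled
analytically (the H term vanishes). `bc_net` is clamped at zero *before*
chemistry; clamped cells are flagged, and the clamped value also enters
CL_max(S) so the sulfur load cannot go negative. K_gibb bins are half-open
[lower, upper): a value exactly on a printed boundary falls in the
higher-OM (lower K_gibb) bin.

The critical N leaching is Q × [N]_crit per ecosystem type. Organic-acid
ANC, bicarbonate leaching and Al complexation beyond gibbsite are not part
of this formulation.

## Parameters not fixed by the method

Baseline weathering rates per soil type, (Bc/Al)_crit, [N]_crit and the
biomass fraction / element-content tables are sourced from external
literature in real applications and are not part of the method's printed
rules. The package ships implementer-chosen placeholder defaults —
(Bc/Al)_crit 0.8–1.0, [N]_crit 0.2–0.4 mg N L⁻¹, p_harvest 0.2–0.5,
element contents of a few tenths of a percent — spanning common
critical-load literature ranges, all overridable from the YAML run config
(`critloads params dump` writes them for editing). The config round-trips
bit-exactly.

## Gridded execution

Layers are single-band TIFFs co-registered on one pixel-is-area, row-major,
top-left-origin grid; geometry, nodata and units live as JSON in each
file's ImageDescription tag. No resampling is performed — geometry
mismatches are an error. Arithmetic is float64 end-to-end (float32 on disk
for outputs by default); the vectorized grid run reuses the same
elementwise routines as the scalar per-cell path and is tested to agree to
1e−12 relative on every cell. Output nodata is −9999; an integer bitmask
layer records per-cell flags (1 carbonate, 2 clamped, 4 masked, 8 coarse
f_de), and the run report carries counts, per-output min/median/max, and a
parameter-table hash for provenance.

## Synthetic data

The generator emulates the *statistical structure* the pipeline assumes:
spatially smooth continuous fields (Gaussian-filtered white noise, wrap
mode, rescaled to range), contiguous categorical patches (nearest-seed
Voronoi partitions), simplex-valued texture via a softmax of smooth fields,
ordered moisture triplets, zero-inflated CaCO₃, and a cropland mask taken
as the lowest quantile of a smooth suitability field. Default ranges:
bulk density 0.8–1.8 g cm⁻³, OM 0–40 % (right-skewed), CaCO₃ 0–10 %
(mostly zero), soil N 0.05–1.5 kg m⁻², temperature 266–303 K, NPP
0–1 500 g m⁻² yr⁻¹, runoff 0–1.5 m yr⁻¹, Bc deposition 0–2 keq ha⁻¹ yr⁻¹,
cropland fraction 0.15 — ranges a practitioner would call plausible for a
large temperate-to-tropical domain. Baseline weathering rates per synthetic
soil type are drawn once per run in 0.1–2.0 keq ha⁻¹ yr⁻¹ and recorded in
the generated parameter file. Everything is deterministic given the seed.

What it does **not** emulate: real geography, spatial covariance between
variables (e.g. texture–drainage correlation), measurement error, or any
calibration to real maps. Green tests on synthetic stacks therefore
demonstrate correctness of the computation and its invariants, not the
realism of any particular national map.

## Problem sizes and numerics

The test suite runs grids of 30×30 to 100×100 cells (the invariant sweep
uses 100×100; the scalar-vs-vectorized comparison 50×50), sizes chosen so
the full suite completes in seconds while exercising every code path,
including masked, clamped, carbonate and coarse-soil cells. The bisection
oracle uses Brent's method on [H] with 1e−15 relative tolerance. Degenerate
inputs: Q = 0 handled analytically; gravel = 1 gives SSA = 0 and hence zero
silicate weathering; theta_wilt ≥ theta_hold, texture sums off by more than
2 %, or any nodata input masks the cell.

## Known limitations

- The Eq.-level double appearance of bulk density (inside SSA and in the
  1.1×1.2 normalization) is reproduced as printed, not corrected.
- Whether baseline rates are per unit mass or volume is not specified by
  the method; they are treated as opaque per-soil-type fluxes.
- Exceedance against deposition scenarios, the critical-load function
  geometry, atmospheric transport and reprojection/tiling are out of scope.
- The emission-inventory operation (Bc_k = Σ PM·ω) is a standalone tabular
  utility; gridded Bc deposition is a direct input layer.
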