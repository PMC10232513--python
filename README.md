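# critloads

Steady-state mass-balance (SMB) critical loads of acidity and eutrophication
for soils, computed per grid cell from co-registered soil, vegetation,
climate and deposition layers.

A *critical load* is the highest long-term deposition of an acidifying or
eutrophying compound that does not cause harmful ecosystem effects at steady
state. `critloads` is for researchers and air-quality assessors who need
gridded critical-load maps — or who need to audit one — from standard
national data products (soil type/texture/chemistry, vegetation type, NPP,
runoff, base-cation deposition). A seeded synthetic-data generator produces
complete, internally consistent input stacks, so the whole pipeline is
testable without any external downloads.

## The model

Per cell, with all fluxes in keq ha⁻¹ yr⁻¹:

```
CL_max(S)  = Bc_dep + Bc_w − Bc_u − ANC_le,crit
CL_min(N)  = N_u + N_i
CL_max(N)  = CL_min(N) + CL_max(S) / (1 − f_de)
CL_nut(N)  = CL_min(N) + N_le,crit / (1 − f_de)
```

where Bc = Ca + Mg + K (Na excluded: plants do not take it up), and

- **Bc_w** — base-cation weathering: a per-soil-type baseline rate at
  standard conditions (281 K, bulk density 1.2 g cm⁻³, SSA 1.1×10⁶ m² m⁻³)
  corrected for moisture (C_sw ∈ [0.7, 1.3]), specific surface area
  (SSA from texture, gravel and density) and temperature
  (exp(3600/T − 3600/281)). Calcareous soils (> 0.5 % CaCO₃) instead get
  CaCO₃(%) × 0.82 keq ha⁻¹ yr⁻¹ outright.
- **Bc_u, N_u** — net growth uptake, NPP × harvestable biomass fraction ×
  element content, converted to charge equivalents.
- **N_i** — long-term N immobilization, soil N pool / soil age
  (1 500 yr skeletal-primitive, 130 000 yr ferralisol, 5 000 yr other).
- **f_de** — denitrification fraction: observation-based per forest type
  (0.65 / 0.20 / 0.25 / 0.35); elsewhere linear in the 7-level drainage
  scale from 0 to 0.8, capped at 0.1 on coarse soils (SSA < 2×10⁶ m² m⁻³).
- **ANC_le,crit** — acceptable acidity leaching at the point where the
  soil-solution molar Bc:Al ratio sits at its ecosystem-critical value under
  the gibbsite equilibrium [Al] = K_gibb[H]³, with K_gibb stepped by soil
  organic matter (9500 … 9.5 m⁶ eq⁻²):
  `ANC_le,crit = −Q^(2/3)·(1.5·Bc_net/(K_gibb·(Bc/Al)_crit))^(1/3) − 1.5·Bc_net/(Bc/Al)_crit`.
- **N_le,crit** — runoff Q times the ecosystem's critical N concentration.

Cropland and unvegetated cells are masked: critical loads are undefined
there by construction.

## Worked example

```python
import critloads as cl

fx = cl.worked_fixtures()["cellA"]   # subtropical forest cell, standard conditions
out = cl.compute_cell(fx.cell, fx.params)
print(f"CL_max(S) = {out.cl_max_s:.3f} keq/ha/yr")
print(f"CL_min(N) = {out.cl_min_n:.3f} keq/ha/yr")
print(f"CL_max(N) = {out.cl_max_n:.3f} keq/ha/yr")
print(f"CL_nut(N) = {out.cl_nut_n:.3f} keq/ha/yr")
```

prints

```
CL_max(S) = 1.532 keq/ha/yr
CL_min(N) = 0.755 keq/ha/yr
CL_max(N) = 3.112 keq/ha/yr
CL_nut(N) = 0.887 keq/ha/yr
```

This cell sees 0.2 keq deposition, weathers 0.35, and stores 0.05 in wood,
so 0.5 keq of net base cations support an acceptable acidity leaching of
−1.032 keq, giving the 1.532 keq sulfur ceiling. Uptake (0.75) plus
immobilization (0.005) set the 0.755 keq nitrogen floor; the subtropical
denitrification fraction 0.35 levers the sulfur ceiling into the 3.112 keq
nitrogen ceiling, and the 0.086 keq acceptable N leaching into the 0.887 keq
nutrient-nitrogen load.

The same computation runs vectorized over a grid from the shell:

```sh
critloads synth demo --size 50 --seed 12   # synthetic input directory
critloads run demo demo_out                # writes clmaxs/clminn/clmaxn/clnutn
critloads params dump                      # built-in parameter tables as YAML
critloads report demo_out                  # run report (counts, summaries)
```

Outputs are single-band TIFFs (nodata −9999) plus an integer flag bitmask
layer recording carbonate / clamped / masked / coarse-f_de cells.

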