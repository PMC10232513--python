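"""The four load equations and the end-to-end per-cell computation."""

import dataclasses

import pytest

import critloads as cl
from critloads.critical_loads import assemble_loads, compute_fluxes


def _fluxes(**kw):
    base = dict(bc_dep=0.0, bc_w=0.0, bc_u=0.0, n_u=0.0, n_i=0.0,
                f_de=0.0, anc_le_crit=0.0, n_le_crit=0.0)
    base.update(kw)
    return cl.FluxSet(**base)


class TestLoadEquations:
    def test_all_zero(self):
        f = _fluxes()
        assert cl.cl_max_s(f) == 0.0
        assert cl.cl_min_n(f) == 0.0
        assert cl.cl_max_n(f, 0.0) == 0.0
        assert cl.cl_nut_n(f) == 0.0

    def test_cl_max_s_worked_example(self):
        f = _fluxes(bc_dep=0.2, bc_w=0.35, bc_u=0.05, anc_le_crit=-1.032)
        assert cl.cl_max_s(f) == pytest.approx(1.532, rel=1e-9)

    def test_cl_max_s_clamped_boundary(self):
        f = _fluxes(bc_dep=0.2, bc_w=0.3, bc_u=0.5, anc_le_crit=0.0)
        assert cl.cl_max_s(f) == 0.0

    def test_cl_min_n_sums(self):
        assert cl.cl_min_n(_fluxes(n_u=0.75, n_i=0.005)) == pytest.approx(0.755)
        assert cl.cl_min_n(_fluxes(n_i=0.3)) == pytest.approx(0.3)

    def test_cl_max_n_leverage(self):
        f = _fluxes(n_u=0.75, n_i=0.005, f_de=0.35)
        assert cl.cl_max_n(f, 1.532) == pytest.approx(0.755 + 1.532 / 0.65,
                                                      abs=1e-9)
        assert cl.cl_max_n(_fluxes(f_de=0.0, n_u=0.5), 2.0) == pytest.approx(2.5)
        assert cl.cl_max_n(_fluxes(n_u=0.5), 0.0) == pytest.approx(0.5)

    def test_cl_nut_n(self):
        f = _fluxes(n_u=0.75, n_i=0.005, f_de=0.35, n_le_crit=0.0857)
        assert cl.cl_nut_n(f) == pytest.approx(0.755 + 0.0857 / 0.65, abs=1e-9)
        assert cl.cl_nut_n(_fluxes(n_u=0.3, n_le_crit=0.0)) == pytest.approx(0.3)
        assert cl.cl_nut_n(_fluxes(n_u=0.3, n_le_crit=1.0)) == pytest.approx(1.3)

    def test_fde_at_one_rejected(self):
        with pytest.raises(cl.InvalidInputError):
            cl.FluxSet(0, 0, 0, 0, 0, f_de=1.0, anc_le_crit=0, n_le_crit=0)


class TestComputeCell:
    def test_worked_cell_a_end_to_end(self, fixtures):
        fx = fixtures["cellA"]
        out = cl.compute_cell(fx.cell, fx.params)
        e = fx.expected
        assert out.cl_max_s == pytest.approx(e["cl_max_s"], rel=e["rtol"])
        assert out.cl_min_n == pytest.approx(e["cl_min_n"], rel=e["rtol"])
        assert out.cl_max_n == pytest.approx(e["cl_max_n"], rel=e["rtol"])
        assert out.cl_nut_n == pytest.approx(e["cl_nut_n"], rel=e["rtol"])
        assert out.flags == cl.CellFlag.NONE

    def test_calcareous_cell_uses_carbonate_weathering(self, fixtures):
        fx = fixtures["calcareous"]
        f = compute_fluxes(fx.cell, fx.params)
        assert f.bc_w == pytest.approx(0.82)
        assert f.flags & cl.CellFlag.CARBONATE

    def test_cropland_cell_is_nodata(self, fixtures):
        fx = fixtures["cropland"]
        out = cl.compute_cell(fx.cell, fx.params)
        assert out.is_masked
        assert (out.cl_max_s, out.cl_min_n, out.cl_max_n, out.cl_nut_n) == \
            (cl.NODATA,) * 4

    def test_coarse_soil_fde_override(self, fixtures):
        fx = fixtures["coarse_poorly_drained"]
        f = compute_fluxes(fx.cell, fx.params)
        assert f.f_de == pytest.approx(0.1)
        assert f.flags & cl.CellFlag.COARSE_FDE

    def test_composition_equals_manual_stage_chaining(self, fixtures):
        """compute_cell output is bit-identical to chaining the stages."""
        fx = fixtures["cellA"]
        f = compute_fluxes(fx.cell, fx.params)
        manual = assemble_loads(f)
        auto = cl.compute_cell(fx.cell, fx.params)
        assert dataclasses.astuple(manual) == dataclasses.astuple(auto)

    def test_zero_flux_cell_reduces_to_immobilization(self, fixtures):
        fx = fixtures["cellA"]
        cell = dataclasses.replace(fx.cell, npp=0.0, bc_dep=0.0)
        params = fx.params
        zero_soil = dataclasses.replace(params.soil(cell.soil_type), bcw0=0.0)
        params = cl.ParameterSet(params.constants,
                                 {**params.soils, cell.soil_type: zero_soil},
                                 params.vegetation, params.criteria)
        out = cl.compute_cell(cell, params)
        f = compute_fluxes(cell, params)
        assert out.cl_max_s == 0.0
        assert out.cl_min_n == pytest.approx(f.n_i, rel=1e-12)

    def test_monotone_in_bc_dep(self, fixtures):
        """CL_max(S) rises at least one-for-one with Bc deposition."""
        fx = fixtures["cellA"]
        deps = [0.0, 0.1, 0.5, 1.0, 2.0]
        vals = [cl.compute_cell(dataclasses.replace(fx.cell, bc_dep=d),
                                fx.params).cl_max_s for d in deps]
        for (d0, v0), (d1, v1) in zip(zip(deps, vals), zip(deps[1:], vals[1:])):
            assert v1 - v0 >= (d1 - d0) * (1.0 - 1e-9)
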