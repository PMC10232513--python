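"""Layer-stack I/O, co-registration checks, and the gridded pipeline."""

import numpy as np
import pytest

import critloads as cl
from critloads.raster_pipeline import (
    OUTPUT_LAYERS,
    cell_from_stack,
    load_stack,
    run_pipeline,
    write_stack,
)


def test_write_read_round_trip_is_exact(tmp_path, small_grid):
    stack, _ = small_grid
    write_stack(stack, tmp_path, dtype=np.float64)
    back = load_stack(tmp_path)
    assert back.checksum() == stack.checksum()
    assert back.transform == stack.transform
    assert back.units["runoff"] == "m/yr"


def test_two_identical_layers_stack(tmp_path):
    a = np.arange(12, dtype=np.float64).reshape(3, 4)
    s = cl.LayerStack({"x": a, "y": a * 2.0})
    write_stack(s, tmp_path)
    assert set(load_stack(tmp_path).layers) == {"x", "y"}


def test_shifted_transform_is_geometry_error(tmp_path):
    a = np.zeros((3, 4))
    write_stack(cl.LayerStack({"x": a}, transform=(1, 0, 0, 0, -1, 0)),
                tmp_path)
    write_stack(cl.LayerStack({"y": a}, transform=(1, 0, 500.0, 0, -1, 0)),
                tmp_path)
    with pytest.raises(cl.GeometryError, match="y"):
        load_stack(tmp_path)


def test_shape_mismatch_is_geometry_error():
    with pytest.raises(cl.GeometryError):
        cl.LayerStack({"x": np.zeros((3, 4)), "y": np.zeros((4, 3))})


def test_missing_required_layer(small_grid):
    stack, params = small_grid
    broken = cl.LayerStack({k: v for k, v in stack.layers.items()
                            if k != "runoff"},
                           transform=stack.transform)
    with pytest.raises(cl.ConfigurationError, match="runoff"):
        run_pipeline(broken, params)


def test_vectorized_equals_scalar_per_cell(small_grid):
    """The gridded run reproduces the scalar per-cell path on every cell."""
    stack, params = small_grid
    out, _ = run_pipeline(stack, params)
    names = ("cl_max_s", "cl_min_n", "cl_max_n", "cl_nut_n")
    for row in range(stack.shape[0]):
        for col in range(stack.shape[1]):
            res = cl.compute_cell(cell_from_stack(stack, row, col), params)
            assert int(out["flags"][row, col]) == int(res.flags)
            for layer, attr in zip(OUTPUT_LAYERS, names):
                got = out[layer][row, col]
                want = getattr(res, attr)
                if want == cl.NODATA:
                    assert got == cl.NODATA
                else:
                    assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


def test_same_seed_runs_are_checksum_identical():
    cfg = cl.SynthConfig(nrows=50, ncols=50, seed=11)
    out1, rep1 = run_pipeline(*cl.generate_grid(cfg))
    out2, rep2 = run_pipeline(*cl.generate_grid(cfg))
    assert out1.checksum() == out2.checksum()
    assert rep1 == rep2


def test_cropland_cells_are_nodata_in_all_outputs(small_grid):
    stack, params = small_grid
    out, _ = run_pipeline(stack, params)
    crop = np.isin(stack["veg_type"], [k for k, v in params.vegetation.items()
                                       if v.is_cropland_or_bare])
    assert crop.any()
    for name in OUTPUT_LAYERS:
        assert np.all(out[name][crop] == cl.NODATA)
        assert np.all((out["flags"][crop].astype(int)
                       & cl.CellFlag.MASKED) > 0)


def test_all_cropland_grid_fully_masked():
    cfg = cl.SynthConfig(nrows=10, ncols=10, seed=2, cropland_fraction=1.0)
    stack, params = cl.generate_grid(cfg)
    out, report = run_pipeline(stack, params)
    assert report["n_masked"] == 100
    for name in OUTPUT_LAYERS:
        assert np.all(out[name] == cl.NODATA)


def test_nodata_inputs_propagate(small_grid):
    stack, params = small_grid
    layers = {k: v.copy() for k, v in stack.layers.items()}
    layers["npp"][4, 5] = stack.nodata
    layers["runoff"][6, 2] = np.nan
    poked = cl.LayerStack(layers, transform=stack.transform,
                          nodata=stack.nodata, units=stack.units)
    out, _ = run_pipeline(poked, params)
    for name in OUTPUT_LAYERS:
        assert out[name][4, 5] == cl.NODATA
        assert out[name][6, 2] == cl.NODATA


def test_report_counts_and_summary(small_grid):
    stack, params = small_grid
    out, report = run_pipeline(stack, params)
    assert report["n_cells"] == 900
    n_masked = int((out["flags"].astype(int) & cl.CellFlag.MASKED > 0).sum())
    assert report["n_masked"] == n_masked
    valid = out["clmaxs"] != cl.NODATA
    assert report["summary"]["clmaxs"]["min"] == pytest.approx(
        float(out["clmaxs"][valid].min()))
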