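"""Weathering corrections: clay factor, SSA, moisture, temperature,
silicate vs carbonate pathways."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import critloads as cl
from critloads.weathering import ssa_from_fields

REF = cl.GlobalConstants()


@pytest.mark.parametrize(
    "x, expected, tol",
    [
        (0.0, 1.0, 0.0),
        (1.0, 1.0 - 1.0 / 1.35, 1e-12),
        (0.35, 1.0 - 0.35**2.5 / (0.35**2.5 + 0.35), 1e-12),
    ],
)
def test_clay_factor_values(x, expected, tol):
    assert cl.clay_factor(x) == pytest.approx(expected, abs=tol)


def test_clay_factor_strictly_decreasing_in_unit_interval():
    xs = np.linspace(0, 1, 101)
    fs = cl.clay_factor(xs)
    assert np.all(np.diff(fs) < 0)
    assert np.all((fs > 0) & (fs <= 1))
    with pytest.raises(cl.InvalidInputError):
        cl.clay_factor(1.1)


@pytest.mark.parametrize(
    "texture, expected",
    [
        (cl.TextureProfile(0, 1, 0, gravel=0, rho_soil=1.2), 2.64),
        (cl.TextureProfile(1, 0, 0, gravel=0.5, rho_soil=1.0), 0.15),
        (cl.TextureProfile(0.4, 0.4, 0.2, gravel=1.0, rho_soil=1.5), 0.0),
    ],
)
def test_specific_surface_area_examples(texture, expected):
    assert cl.specific_surface_area(texture) == pytest.approx(expected, rel=1e-12)


@settings(deadline=None, max_examples=100)
@given(
    st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
    st.floats(0, 1), st.floats(0.2, 2.5),
)
def test_ssa_matches_term_by_term_recomputation(a, b, c, gravel, rho):
    """SSA equals an independent term-by-term evaluation to 1e-12 relative."""
    total = a + b + c
    if total == 0:
        return
    sand, silt, clay = a / total, b / total, c / total
    texture = cl.TextureProfile(sand, silt, clay, gravel, rho)
    fclay = 1.0 - clay**2.5 / (clay**2.5 + 0.35)
    expected = (0.3 * texture.x_sand + 2.2 * texture.x_silt
                + 8.0 * fclay * texture.x_clay) * (1.0 - gravel) * rho
    got = cl.specific_surface_area(texture)
    assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)
    assert got >= 0


def test_texture_renormalization_and_rejection():
    t = cl.TextureProfile(0.5, 0.3, 0.21)  # sums to 1.01, within 2%
    assert t.x_sand + t.x_silt + t.x_clay == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(cl.InvalidInputError):
        cl.TextureProfile(0.5, 0.3, 0.3)  # 1.10, outside tolerance


def test_moisture_factor_bounds_and_midpoint():
    assert cl.moisture_factor(cl.MoistureState(0.05, 0.1, 0.3)) == 0.7
    assert cl.moisture_factor(cl.MoistureState(0.5, 0.1, 0.3)) == 1.3
    assert cl.moisture_factor(cl.MoistureState(0.2, 0.1, 0.3)) == pytest.approx(1.0)
    with pytest.raises(cl.InvalidInputError):
        cl.MoistureState(0.2, 0.3, 0.3)


@settings(deadline=None, max_examples=100)
@given(st.floats(0, 1), st.floats(0, 1))
def test_moisture_factor_monotone(theta_a, theta_b):
    m = lambda t: cl.moisture_factor(cl.MoistureState(t, 0.1, 0.4))
    lo, hi = sorted([theta_a, theta_b])
    assert m(lo) <= m(hi)
    assert 0.7 <= m(lo) <= 1.3


def test_temperature_factor_reference_and_examples():
    assert cl.temperature_factor(281.0) == 1.0
    assert cl.temperature_factor(291.0) == pytest.approx(
        math.exp(3600 / 291 - 3600 / 281), rel=1e-12)
    assert cl.temperature_factor(291.0) == pytest.approx(0.6438, abs=1e-3)
    assert cl.temperature_factor(271.0) == pytest.approx(
        math.exp(3600 / 271 - 3600 / 281), rel=1e-12)
    with pytest.raises(cl.InvalidInputError):
        cl.temperature_factor(-5.0)


def test_temperature_factor_direction_against_brute_force_grid():
    """exp(A/T - A/281) falls as T rises: warmer soils get smaller factors."""
    ts = np.linspace(230.0, 330.0, 201)
    factors = cl.temperature_factor(ts)
    brute = np.exp(3600.0 / ts - 3600.0 / 281.0)
    np.testing.assert_allclose(factors, brute, rtol=1e-14)
    assert np.all(np.diff(factors) < 0)


def test_silicate_weathering_identity_and_linearity():
    texture = cl.TextureProfile(0, 1, 0, gravel=0.5, rho_soil=1.2)  # SSA 1.32
    midpoint = cl.MoistureState(0.2, 0.1, 0.3)                      # C_sw 1
    w = cl.silicate_weathering(0.5, texture, midpoint, 281.0)
    assert w == pytest.approx(0.5, rel=1e-12)

    silt = cl.TextureProfile(0, 1, 0, gravel=0, rho_soil=1.2)       # SSA 2.64
    assert cl.silicate_weathering(0.5, silt, midpoint, 281.0) == \
        pytest.approx(1.0, rel=1e-12)
    assert cl.silicate_weathering(0.0, silt, midpoint, 281.0) == 0.0
    # homogeneous of degree 1 in bcw0
    assert cl.silicate_weathering(1.4, silt, midpoint, 281.0) == \
        pytest.approx(2.8 * cl.silicate_weathering(0.5, silt, midpoint, 281.0),
                      rel=1e-12)


@settings(deadline=None, max_examples=100)
@given(
    st.floats(0, 3), st.floats(0, 1), st.floats(0.2, 2.5),
    st.floats(0, 0.6), st.floats(240, 320),
)
def test_weathering_non_negative_monotone_in_moisture(bcw0, gravel, rho,
                                                      theta, temp):
    texture = cl.TextureProfile(0.4, 0.4, 0.2, gravel, rho)
    w = cl.silicate_weathering(bcw0, texture,
                               cl.MoistureState(theta, 0.1, 0.4), temp)
    wetter = cl.silicate_weathering(bcw0, texture,
                                    cl.MoistureState(min(theta + 0.1, 1.0),
                                                     0.1, 0.4), temp)
    assert w >= 0
    assert wetter >= w - 1e-15 * abs(w)


def test_carbonate_rule_threshold_and_slope():
    assert cl.carbonate_weathering(0.4) is None
    assert cl.carbonate_weathering(0.5) is None  # strictly "higher than 0.5%"
    assert cl.carbonate_weathering(1.0) == pytest.approx(0.82)
    assert cl.carbonate_weathering(2.5) == pytest.approx(2.05)
    with pytest.raises(cl.InvalidInputError):
        cl.carbonate_weathering(-0.1)


def test_effective_weathering_selects_pathway():
    texture = cl.TextureProfile(0, 1, 0, gravel=0.5, rho_soil=1.2)
    midpoint = cl.MoistureState(0.2, 0.1, 0.3)
    flux, pathway = cl.effective_weathering(0.5, texture, midpoint, 281.0, 1.0)
    assert (flux, pathway) == (pytest.approx(0.82), "carbonate")
    flux, pathway = cl.effective_weathering(0.5, texture, midpoint, 281.0, 0.5)
    assert pathway == "silicate"
    assert flux == pytest.approx(0.5, rel=1e-12)
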