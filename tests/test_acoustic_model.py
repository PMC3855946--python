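import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctus.acoustic_model import (
    AcousticParams,
    attenuate,
    beam_cosines,
    classify_pair,
    lambert_response,
    local_response_weight,
    propagate_all,
    propagate_scanline,
    reflection_coefficient,
    surface_normal_2d,
    transmission_coefficient,
)
from ctus.sector_geometry import ScanlineSet, SectorGeometry

P = AcousticParams()


# ---------------------------------------------------------------------------
# reflection / transmission
# ---------------------------------------------------------------------------


def test_reflection_identity_interface():
    assert reflection_coefficient(1.5, 1.5) == 0.0


def test_reflection_hand_value():
    assert reflection_coefficient(1.0, 3.0) == pytest.approx(0.25)
    assert transmission_coefficient(1.0, 3.0) == pytest.approx(0.75)


def test_reflection_rejects_nonpositive():
    with pytest.raises(ValueError):
        reflection_coefficient(0.0, 1.0)


@settings(max_examples=100, deadline=None)
@given(z1=st.floats(1e-3, 1e4), z2=st.floats(1e-3, 1e4))
def test_energy_conservation_and_symmetry(z1, z2):
    r = reflection_coefficient(z1, z2)
    t = transmission_coefficient(z1, z2)
    assert abs(r + t - 1.0) < 1e-12
    assert r == pytest.approx(reflection_coefficient(z2, z1), abs=1e-15)


# ---------------------------------------------------------------------------
# interface classification and weights
# ---------------------------------------------------------------------------


def test_classify_subthreshold_pair_is_none():
    i1, i2 = 1024 + 50.0, 1024 + 50.5
    assert abs(i2 - i1) / (i1 + i2) < P.reflect_threshold
    assert classify_pair(i1, i2, 50.0, 50.5, P) == "none"


def test_classify_bone_and_air_pairs():
    assert classify_pair(1074.0, 2024.0, 50.0, 1000.0, P) == "bone"
    assert classify_pair(1074.0, 124.0, 50.0, -900.0, P) == "air"
    # both sides inside the medium: no clamp
    assert classify_pair(2024.0, 2030.0, 1000.0, 1006.0, P) != "bone"


def test_weight_soft_identity_is_zero():
    assert local_response_weight(1100.0, 1100.0, "soft", P) == 0.0


def test_weight_bone_clamp_ignores_intensities():
    assert local_response_weight(1.0, 9999.0, "bone", P) == 0.43
    assert local_response_weight(500.0, 500.0, "bone", P) == 0.43


def test_weight_air_clamp():
    assert local_response_weight(1074.0, 124.0, "air", P) == 0.99


def test_weight_soft_hand_value():
    i1, i2 = 1024 + 50.0, 1024 + 120.0
    expected = ((120.0 - 50.0) / (2048 + 170.0)) ** 2
    assert local_response_weight(i1, i2, "soft", P) == pytest.approx(expected)


def test_threshold_jump_is_quantifiably_negligible():
    """Crossing the 0.1% relative-difference threshold turns alpha on, and
    the discontinuity magnitude is bounded by threshold^2."""
    i1 = 1000.0
    eps = P.reflect_threshold
    i2 = i1 * (1 + 2 * eps) / (1 - 2 * eps) * (1 + 1e-9)  # just above
    ratio = abs(i2 - i1) / (i1 + i2)
    assert ratio >= eps
    alpha = local_response_weight(i1, i2, "soft", P)
    assert alpha <= (2 * ratio) ** 2
    assert alpha <= 4 * eps**2 * 1.1  # jump magnitude ~ threshold^2


# ---------------------------------------------------------------------------
# surface normals
# ---------------------------------------------------------------------------


def test_normal_horizontal_edge_along_depth():
    grid = np.zeros((8, 8))
    grid[4:, :] = 10.0  # jump between rows
    n = surface_normal_2d(grid, 4, 4)
    assert abs(n[0]) == pytest.approx(1.0)
    assert n[1] == pytest.approx(0.0, abs=1e-12)


def test_normal_vertical_edge_perpendicular():
    grid = np.zeros((8, 8))
    grid[:, 4:] = 10.0
    n = surface_normal_2d(grid, 4, 4)
    assert abs(n[1]) == pytest.approx(1.0)


def test_normal_45_degree_ramp():
    rows, cols = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
    ramp = (rows + cols).astype(float)
    n = surface_normal_2d(ramp, 8, 8)
    angle = np.degrees(np.arctan2(n[1], n[0]))
    assert angle == pytest.approx(45.0, abs=1.0)


def test_flat_region_cosine_is_one():
    cos = beam_cosines(np.full((10, 10), 5.0))
    assert np.all(cos == 1.0)


# ---------------------------------------------------------------------------
# Lambert and attenuation closed forms
# ---------------------------------------------------------------------------


def test_lambert_values():
    assert lambert_response(0.25, 100.0, 0.5) == pytest.approx(12.5)
    assert lambert_response(0.25, 100.0, 1.0) == pytest.approx(25.0)
    assert lambert_response(0.25, 100.0, 0.0) == 0.0


def test_attenuate_values():
    assert attenuate(100.0, 0.1, 0.0) == pytest.approx(100.0)
    assert attenuate(100.0, 0.0, 50.0) == pytest.approx(100.0)
    assert attenuate(100.0, 0.1, 5.0) == pytest.approx(100.0 * np.exp(-1.0))
    with pytest.raises(ValueError):
        attenuate(100.0, 0.1, -1.0)


# ---------------------------------------------------------------------------
# scanline propagation
# ---------------------------------------------------------------------------


def quiet(**kw):
    return AcousticParams(speckle_sigma=0.0, scatter_gain=0.0, **kw)


def test_constant_column_no_noise_gives_zero_echo():
    profile = propagate_scanline(np.full(30, 50.0), None, None, quiet(), 1.0)
    assert np.all(profile.amplitudes == 0.0)


def test_two_interface_column_matches_hand_computed_closed_form():
    """A soft interface followed by a bone interface, checked against the
    echo formula alpha * U_in * cos(theta) * exp(-2 A) evaluated by hand."""
    p = quiet()
    col = np.array([50.0, 50.0, 120.0, 120.0, 1000.0, 1000.0])
    step = 1.5
    profile = propagate_scanline(col, None, None, p, step)
    s = np.maximum(col + p.hu_shift, 1.0)
    a_soft = ((s[2] - s[1]) / (s[2] + s[1])) ** 2
    a_bone = 0.43
    A = np.cumsum([0.0, 0.0, a_soft, 0.0, a_bone, 0.0]) * step
    expected = np.array(
        [0.0, 0.0,
         a_soft * p.u_in * np.exp(-2 * A[2]),
         0.0,
         a_bone * p.u_in * np.exp(-2 * A[4]),
         0.0]
    )
    np.testing.assert_allclose(profile.amplitudes, expected, atol=1e-9)
    np.testing.assert_allclose(profile.cumulative_attenuation, A, atol=1e-12)


def test_bone_sample_shadows_deeper_echoes():
    rng = np.random.default_rng(4)
    col = 50.0 + rng.normal(0, 6.0, 61)  # textured soft tissue
    col[30] = 1000.0  # one bone sample midway
    p = AcousticParams(speckle_sigma=0.0, scatter_gain=20.0)
    # 2 mm sampling: two clamped pairs give exp(-2 * 2*0.43*2) ~ 0.03
    profile = propagate_scanline(col, None, None, p, 2.0)
    shallower = profile.amplitudes[3:28].sum()
    deeper = profile.amplitudes[34:].sum()
    assert deeper < 0.05 * shallower


def test_propagation_determinism():
    col = 50.0 + np.random.default_rng(0).normal(0, 8, 40)
    p = AcousticParams(speckle_sigma=0.4, noise_seed=123)
    a = propagate_scanline(col, None, None, p, 1.0)
    b = propagate_scanline(col, None, None, p, 1.0)
    np.testing.assert_array_equal(a.amplitudes, b.amplitudes)


def test_amplitudes_bounded_and_attenuation_monotone():
    rng = np.random.default_rng(1)
    col = rng.uniform(-1000, 1500, 80)
    p = AcousticParams(speckle_sigma=0.5, scatter_gain=50.0)
    profile = propagate_scanline(col, None, None, p, 1.0)
    assert profile.amplitudes.max() <= p.u_in + 1e-12
    assert profile.amplitudes.min() >= 0.0
    assert np.all(np.diff(profile.cumulative_attenuation) >= -1e-15)


def test_vessel_suppression_darkens_lumen():
    rng = np.random.default_rng(2)
    col = 55.0 + rng.normal(0, 8, 50)
    nu = np.zeros(50)
    nu[20:30] = 1.0
    p = AcousticParams(speckle_sigma=0.0, scatter_gain=20.0, vessel_suppress=0.9)
    with_v = propagate_scanline(col, nu, None, p, 1.0)
    without = propagate_scanline(col, None, None, p, 1.0)
    assert with_v.amplitudes[20:30].sum() < 0.2 * without.amplitudes[20:30].sum()
    np.testing.assert_allclose(with_v.amplitudes[:18], without.amplitudes[:18])


def test_short_column_rejected():
    with pytest.raises(ValueError):
        propagate_scanline(np.array([1.0]), None, None, quiet(), 1.0)


# ---------------------------------------------------------------------------
# grid propagation
# ---------------------------------------------------------------------------


def make_scanlines(grid):
    m, n = grid.shape
    g = SectorGeometry(fov=60.0, r_short=10.0, r_long=10.0 + (m - 1) * 1.2,
                       m=m, n=n)
    return ScanlineSet(rect=grid, geometry=g, depth_step=g.depth_step)


def test_propagate_all_constant_grid_is_zero():
    rect = make_scanlines(np.full((20, 8), 60.0))
    out = propagate_all(rect, None, quiet())
    assert np.all(out == 0.0)


def test_propagate_all_identical_columns_equal_without_speckle():
    col = 50.0 + np.random.default_rng(3).normal(0, 8, 25)
    grid = np.tile(col[:, None], (1, 6))
    rect = make_scanlines(grid)
    p = AcousticParams(speckle_sigma=0.0, scatter_gain=20.0)
    out = propagate_all(rect, None, p)
    for j in range(1, 6):
        np.testing.assert_allclose(out[:, j], out[:, 0])


def test_propagate_all_shape_mismatch_rejected():
    rect = make_scanlines(np.zeros((10, 4)))
    with pytest.raises(ValueError):
        propagate_all(rect, np.zeros((10, 5)), quiet())


def test_propagate_all_nonnegative_and_seed_deterministic():
    rng = np.random.default_rng(5)
    grid = 50.0 + rng.normal(0, 8, (30, 10))
    rect = make_scanlines(grid)
    p = AcousticParams(speckle_sigma=0.3, noise_seed=77)
    a = propagate_all(rect, None, p)
    b = propagate_all(rect, None, p)
    np.testing.assert_array_equal(a, b)
    assert a.min() >= 0.0
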