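import numpy as np
import pytest

import ctus
from ctus.sector_geometry import (
    ProbePose,
    SectorGeometry,
    SliceImage,
    build_correspondences,
    extract_sector_slice,
    fit_sector_transforms,
    map_to_sector,
    resample_to_rectangle,
    tps_apply,
    tps_bending_energy,
    tps_fit,
)
from ctus.volume_io import CTVolume


# ---------------------------------------------------------------------------
# geometry / correspondences
# ---------------------------------------------------------------------------


def test_geometry_invariants():
    with pytest.raises(ValueError):
        SectorGeometry(fov=200.0)
    with pytest.raises(ValueError):
        SectorGeometry(r_short=50.0, r_long=40.0)
    with pytest.raises(ValueError):
        SectorGeometry(m=1)


def test_correspondences_four_corners():
    g = SectorGeometry(fov=90.0, r_short=0.0, r_long=100.0, m=2, n=2)
    p, q = build_correspondences(g)
    s = np.sqrt(2) / 2
    expected = {
        (0.0, 0.0): (0.0, 0.0),          # rect (col 0, row 0) -> apex
        (1.0, 0.0): (0.0, 0.0),          # r=0 collapses to the apex
        (0.0, 1.0): (-100 * s, 100 * s),  # -45 degrees, r=100
        (1.0, 1.0): (100 * s, 100 * s),   # +45 degrees
    }
    for pi, qi in zip(p, q):
        np.testing.assert_allclose(pi, expected[tuple(qi)], atol=1e-9)


def test_correspondences_middle_column_on_axis():
    g = SectorGeometry(fov=60.0, r_short=10.0, r_long=50.0, m=5, n=5)
    p, q = build_correspondences(g)
    mid = q[:, 0] == 2  # central column
    assert np.abs(p[mid, 0]).max() < 1e-9  # x = 0 along the axis ray
    assert np.all(p[mid, 1] > 0)


def test_correspondences_radius_bounds():
    g = SectorGeometry(fov=75.0, r_short=10.0, r_long=130.0, m=7, n=9)
    p, _ = build_correspondences(g)
    r = np.hypot(p[:, 0], p[:, 1])
    assert r.min() >= g.r_short - 1e-9
    assert r.max() <= g.r_long + 1e-9


# ---------------------------------------------------------------------------
# thin-plate spline
# ---------------------------------------------------------------------------


def lattice(n=5, span=10.0, seed=None):
    x = np.linspace(0, span, n)
    q = np.stack(np.meshgrid(x, x), axis=-1).reshape(-1, 2)
    if seed is not None:
        q = q + np.random.default_rng(seed).normal(0, 0.1, q.shape)
    return q


def test_tps_identity_pairing():
    q = lattice()
    t = tps_fit(q, q, lambda_reg=0.0)
    np.testing.assert_allclose(t.affine, np.eye(3), atol=1e-8)
    assert np.abs(t.warp).max() < 1e-8


def test_tps_recovers_random_affine_vs_lstsq_oracle():
    rng = np.random.default_rng(3)
    q = lattice(seed=5)
    A = rng.normal(size=(2, 2)) + np.eye(2)
    b = rng.normal(size=2)
    p = q @ A.T + b
    t = tps_fit(p, q, lambda_reg=0.0)
    # oracle: direct least-squares affine fit
    X = np.column_stack([q, np.ones(len(q))])
    coef, *_ = np.linalg.lstsq(X, p, rcond=None)
    expected = np.eye(3)
    expected[:2, :2] = coef[:2]
    expected[2, :2] = coef[2]
    np.testing.assert_allclose(t.affine, expected, atol=1e-6)
    assert np.abs(t.warp).max() < 1e-6


def test_tps_exact_interpolation_at_lambda_zero():
    rng = np.random.default_rng(9)
    q = lattice(seed=1)
    p = q + rng.normal(0, 1.5, q.shape)  # non-affine displacement
    t = tps_fit(p, q, lambda_reg=0.0)
    np.testing.assert_allclose(tps_apply(t, q), p, atol=1e-8)


def test_tps_warp_orthogonal_to_affine_space():
    rng = np.random.default_rng(2)
    q = lattice(seed=4)
    p = q + rng.normal(0, 1.0, q.shape)
    t = tps_fit(p, q, lambda_reg=0.0)
    P = np.column_stack([np.ones(len(q)), q])
    assert np.abs(P.T @ t.warp).max() < 1e-8


def test_tps_collinear_landmarks_rejected():
    q = np.stack([np.arange(5.0), 2 * np.arange(5.0)], axis=-1)
    with pytest.raises(np.linalg.LinAlgError):
        tps_fit(q, q)


def test_tps_mismatched_counts_rejected():
    with pytest.raises(ValueError):
        tps_fit(np.zeros((4, 2)), np.zeros((5, 2)))


def test_tps_midpoint_under_pure_affine_fit():
    q = lattice()
    A = np.array([[1.2, 0.3], [-0.1, 0.9]])
    b = np.array([2.0, -1.0])
    p = q @ A.T + b
    t = tps_fit(p, q, lambda_reg=0.0)
    mid = (q[0] + q[7]) / 2
    np.testing.assert_allclose(tps_apply(t, mid[None]), (mid @ A.T + b)[None],
                               atol=1e-6)


def test_tps_bending_energy_nonincreasing_in_lambda():
    rng = np.random.default_rng(8)
    q = lattice(seed=2)
    p = q + rng.normal(0, 2.0, q.shape)
    energies = [tps_bending_energy(tps_fit(p, q, lam))
                for lam in (0.0, 0.1, 1.0, 10.0)]
    assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))


def test_forward_inverse_compose_to_identity_on_lattice():
    g = SectorGeometry(fov=75.0, r_short=10.0, r_long=130.0, m=50, n=40)
    forward, inverse = fit_sector_transforms(g, control=10)
    p, q = build_correspondences(g, control=10)
    round_trip = tps_apply(inverse, tps_apply(forward, q))
    err = np.linalg.norm(round_trip - q, axis=1)
    assert err.max() < 0.1


# ---------------------------------------------------------------------------
# slice extraction
# ---------------------------------------------------------------------------

GEO = SectorGeometry(fov=60.0, r_short=5.0, r_long=60.0, m=45, n=40)


def test_extract_constant_volume_gives_constant_slice():
    vol = CTVolume(np.full((80, 80, 80), 123.0), spacing=(1, 1, 1))
    pose = ProbePose(apex=(40, 5, 40), beam_dir=(0, 1, 0), in_plane=(1, 0, 0))
    sl = extract_sector_slice(vol, pose, GEO, pitch=1.0)
    inside = sl.data[5:-5, 5:-5]
    assert np.all(np.abs(inside - 123.0) < 1e-9)


def test_extract_slice_locates_known_sphere():
    vol = ctus.phantoms.make_sphere_volume(
        dims=(80, 80, 80), radius=8.0, inside_val=200.0, outside_val=0.0
    )
    # sphere center is at (39.5, 39.5, 39.5) mm; probe above it
    pose = ProbePose(apex=(39.5, 4.5, 39.5), beam_dir=(0, 1, 0), in_plane=(1, 0, 0))
    sl = extract_sector_slice(vol, pose, GEO, pitch=0.5)
    # predicted in-slice center: x=0, y = 39.5 - 4.5 = 35
    assert sl.sample(np.array([[0.0, 35.0]]))[0] == pytest.approx(200.0)
    assert sl.sample(np.array([[0.0, 35.0 + 12]]))[0] == pytest.approx(0.0)
    assert sl.sample(np.array([[20.0, 35.0]]))[0] == pytest.approx(0.0)


def test_extract_pose_outside_volume_is_background():
    vol = CTVolume(np.full((20, 20, 20), 77.0), spacing=(1, 1, 1))
    pose = ProbePose(apex=(500, 500, 500), beam_dir=(0, 1, 0), in_plane=(1, 0, 0))
    sl = extract_sector_slice(vol, pose, GEO, background=-1000.0)
    assert np.all(sl.data == -1000.0)


def test_extract_degenerate_directions_rejected():
    vol = CTVolume(np.zeros((8, 8, 8)), spacing=(1, 1, 1))
    pose = ProbePose(apex=(0, 0, 0), beam_dir=(0, 1, 0), in_plane=(0, 2, 0))
    with pytest.raises(ValueError, match="parallel"):
        extract_sector_slice(vol, pose, GEO)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def radial_slice(geometry, pitch=0.5):
    """Synthetic slice whose value is the distance from the apex (mm)."""
    x0, y0, x1, y1 = geometry.bounding_box(4.0)
    xs = x0 + pitch * np.arange(int(np.ceil((x1 - x0) / pitch)) + 1)
    ys = y0 + pitch * np.arange(int(np.ceil((y1 - y0) / pitch)) + 1)
    XX, YY = np.meshgrid(xs, ys)
    data = np.hypot(XX - geometry.apex[0], YY - geometry.apex[1])
    return SliceImage(data=data, origin=(x0, y0), pitch=pitch, geometry=geometry)


def test_resample_constant_slice():
    g = GEO
    forward, _ = fit_sector_transforms(g)
    sl = radial_slice(g)
    sl.data[:] = 5.0
    rect = resample_to_rectangle(sl, g, forward)
    assert rect.rect.shape == (g.m, g.n)
    np.testing.assert_allclose(rect.rect, 5.0, atol=1e-6)
    assert rect.depth_step == pytest.approx((g.r_long - g.r_short) / (g.m - 1))


def test_resample_radial_field_rows_constant_increasing():
    g = GEO
    forward, _ = fit_sector_transforms(g)
    rect = resample_to_rectangle(radial_slice(g), g, forward).rect
    # each row samples a fixed radius r_s + i*step (closed-form polar oracle)
    expected = g.r_short + np.arange(g.m) * g.depth_step
    np.testing.assert_allclose(rect, expected[:, None] * np.ones((1, g.n)),
                               atol=0.5)
    row_spread = rect.max(axis=1) - rect.min(axis=1)
    assert row_spread.max() < 0.5


def test_rect_sector_rect_round_trip_smooth_image():
    g = SectorGeometry(fov=70.0, r_short=10.0, r_long=90.0, m=60, n=50)
    forward, inverse = fit_sector_transforms(g)
    rows, cols = np.meshgrid(np.arange(g.m), np.arange(g.n), indexing="ij")
    smooth = np.sin(rows / 9.0) + np.cos(cols / 7.0)  # dynamic range ~4
    sector_img, mask, origin, pitch = map_to_sector(smooth, g, inverse, pitch=0.5)
    sl = SliceImage(data=sector_img, origin=origin, pitch=pitch, geometry=g)
    back = resample_to_rectangle(sl, g, forward).rect
    interior = np.s_[3:-3, 3:-3]
    err = np.abs(back - smooth)[interior].mean()
    dynamic = smooth.max() - smooth.min()
    assert err < 0.02 * dynamic


# ---------------------------------------------------------------------------
# sector rendering
# ---------------------------------------------------------------------------


def test_map_to_sector_constant_fill():
    g = GEO
    _, inverse = fit_sector_transforms(g)
    img, mask, _, _ = map_to_sector(np.full((g.m, g.n), 9.0), g, inverse)
    np.testing.assert_allclose(img[mask], 9.0, atol=1e-6)
    assert np.all(img[~mask] == 0.0)


def test_map_to_sector_bright_column_is_ray():
    g = SectorGeometry(fov=80.0, r_short=5.0, r_long=80.0, m=60, n=41)
    _, inverse = fit_sector_transforms(g)
    rect = np.zeros((g.m, g.n))
    col = 30
    rect[:, col] = 100.0
    img, mask, origin, pitch = map_to_sector(rect, g, inverse, pitch=0.5)
    # bright pixels should lie near the ray at this column's angle
    expected_angle = -g.fov / 2 + col * g.fov / (g.n - 1)
    ys, xs = np.nonzero(img > 50.0)
    pts = np.stack([origin[0] + pitch * xs, origin[1] + pitch * ys], axis=-1)
    r, ang = g.polar(pts)
    # away from the apex, where one raster pixel no longer spans degrees
    far = r > 15.0
    assert far.any()
    assert np.abs(ang - expected_angle)[far].max() < 3.0  # degrees


def test_sector_mask_area_matches_analytic_formula():
    g = SectorGeometry(fov=75.0, r_short=10.0, r_long=130.0, m=40, n=40)
    _, inverse = fit_sector_transforms(g)
    _, mask, _, pitch = map_to_sector(np.ones((g.m, g.n)), g, inverse, pitch=0.5)
    area = mask.sum() * pitch**2
    expected = g.fov / 360.0 * np.pi * (g.r_long**2 - g.r_short**2)
    assert area == pytest.approx(expected, rel=0.03)
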