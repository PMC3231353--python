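import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import ellipse

from teashoot3d.features import (
    Axis,
    ShootFeatures,
    binarize,
    central_axis,
    chaikin_smooth,
    extract_shoot_features,
    inclination_angle,
    measure_branch,
    measure_leaf,
    reduce_polyline,
    subdivide_curve,
    trace_boundary,
)


# ---------------------------------------------------------------------------
# binarization and boundary following


def test_binarize_mask_identity_and_threshold():
    mask = np.zeros((4, 4), bool)
    mask[1:3, 1:3] = True
    assert np.array_equal(binarize(mask), mask)
    ramp = np.linspace(0, 1, 16).reshape(4, 4)
    out = binarize(ramp, threshold=0.5)
    assert out.sum() == (ramp > 0.5).sum()


def test_binarize_empty_warns():
    with pytest.warns(UserWarning, match="empty"):
        binarize(np.zeros((3, 3), bool))


@pytest.mark.parametrize("n", [3, 5, 8])
def test_square_contour_length(n):
    m = np.zeros((n + 4, n + 4), bool)
    m[2 : 2 + n, 2 : 2 + n] = True
    (contour,) = trace_boundary(m)
    assert len(contour) == 4 * n - 4


def test_single_pixel_contour():
    m = np.zeros((3, 3), bool)
    m[1, 1] = True
    (contour,) = trace_boundary(m)
    assert len(contour) == 1


def test_contour_is_exact_pixel_boundary():
    """The traced contour visits exactly the foreground pixels that have a
    background 4-neighbor."""
    m = np.zeros((40, 40), bool)
    rr, cc = ellipse(20, 20, 12, 8)
    m[rr, cc] = True
    (contour,) = trace_boundary(m)
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    expected = set(map(tuple, np.argwhere(m & ~ndimage.binary_erosion(m, four))))
    assert set(map(tuple, contour.points.tolist())) == expected


def test_contour_closed_and_8_connected():
    m = np.zeros((20, 20), bool)
    m[4:15, 6:17] = True
    (contour,) = trace_boundary(m)
    pts = np.vstack([contour.points, contour.points[:1]])
    steps = np.abs(np.diff(pts, axis=0)).max(axis=1)
    assert np.all(steps == 1)


def test_fill_retrace_round_trip():
    """Filling a traced contour and retracing returns the same contour."""
    m = np.zeros((30, 30), bool)
    rr, cc = ellipse(14, 15, 9, 11)
    m[rr, cc] = True
    (c1,) = trace_boundary(m)
    filled = ndimage.binary_fill_holes(
        np.isin(
            np.arange(900).reshape(30, 30),
            [r * 30 + c for r, c in c1.points],
        )
    )
    (c2,) = trace_boundary(filled)
    assert set(map(tuple, c1.points.tolist())) == set(map(tuple, c2.points.tolist()))


# ---------------------------------------------------------------------------
# curve subdivision


def test_collinear_points_reduce_to_endpoints():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [7.0, 0.0]])
    assert len(subdivide_curve(pts, tol=0.1)) == 2


def test_square_wave_extremes_retained():
    x = np.arange(10, dtype=float)
    y = np.where(x % 2 == 0, 0.0, 5.0)
    pts = np.column_stack([x, y])
    reduced = reduce_polyline(pts, tol=1.0)
    # brute-force deviation check: every input vertex within tol of output
    for p in pts:
        d = min(
            np.min(np.linalg.norm(reduced - p, axis=1)),
            *(
                _seg_dist(p, reduced[i], reduced[i + 1])
                for i in range(len(reduced) - 1)
            ),
        )
        assert d <= 1.0
    assert len(reduced) == len(pts)  # amplitude 5 > tol: all kept


def _seg_dist(p, a, b):
    ab = b - a
    t = np.clip((p - a) @ ab / (ab @ ab), 0, 1)
    return np.linalg.norm(p - (a + t * ab))


def test_chaikin_right_angle_quarter_points():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
    out = chaikin_smooth(pts, n_iters=1)
    expected = np.array([[0.0, 0.0], [0.75, 0.0], [1.0, 0.25], [1.0, 1.0]])
    assert np.allclose(out, expected)


def test_reduction_respects_tolerance():
    rng = np.random.default_rng(0)
    t = np.linspace(0, 2 * np.pi, 200)
    pts = np.column_stack([10 * np.cos(t), 6 * np.sin(t)]) + rng.normal(0, 0.05, (200, 2))
    out = reduce_polyline(pts, tol=0.5)
    assert len(out) <= len(pts)
    for p in pts:
        d = min(_seg_dist(p, out[i], out[i + 1]) for i in range(len(out) - 1))
        assert d <= 0.5 + 1e-9


def test_subdivide_rejects_bad_tol():
    with pytest.raises(ValueError):
        subdivide_curve(np.zeros((3, 2)), tol=0.0)


# ---------------------------------------------------------------------------
# central axis


def test_rectangle_axis_is_centerline():
    m = np.zeros((20, 110), bool)
    m[8:13, 5:105] = True  # 100 x 5
    axis = central_axis(m)
    assert axis.length == pytest.approx(100.0, rel=0.05)
    rows = axis.points[:, 0]
    assert np.all(np.abs(rows - 10.0) < 1.5)


def test_disk_axis_degenerates():
    m = np.zeros((40, 40), bool)
    rr, cc = ellipse(20, 20, 15, 15)
    m[rr, cc] = True
    axis = central_axis(m)
    assert axis.length < 30.0  # well below the diameter


def test_axis_lies_inside_foreground():
    m = np.zeros((60, 120), bool)
    rr, cc = ellipse(30, 60, 18, 55)
    m[rr, cc] = True
    axis = central_axis(m)
    ri = np.clip(np.round(axis.points[:, 0]).astype(int), 0, 59)
    ci = np.clip(np.round(axis.points[:, 1]).astype(int), 0, 119)
    assert m[ri, ci].all()


def test_axis_tracks_true_vein(table1_fixture):
    """The measured central axis stays within 2 px of the rendered vein."""
    fx = table1_fixture
    mask = fx.organ_masks["leaf_1"]
    axis = central_axis(mask)
    tree = cKDTree(fx.true_veins["leaf_1"])
    d, _ = tree.query(axis.points)
    assert d.mean() <= 2.0


# ---------------------------------------------------------------------------
# measurements


def test_ellipse_leaf_measurements():
    m = np.zeros((160, 440), bool)
    rr, cc = ellipse(80, 220, 60, 200)
    m[rr, cc] = True
    axis = central_axis(m)
    ll, lw = measure_leaf(m, axis)
    assert ll == pytest.approx(400.0, rel=0.05)
    assert lw == pytest.approx(120.0, rel=0.05)


def test_circle_length_close_to_width():
    m = np.zeros((60, 60), bool)
    rr, cc = ellipse(30, 30, 20, 20)
    m[rr, cc] = True
    axis = central_axis(m)
    ll, lw = measure_leaf(m, axis)
    assert abs(ll - lw) / lw < 0.25


def test_branch_rectangle_measurements():
    m = np.zeros((70, 340), bool)
    m[10:61, 10:331] = True  # 321 x 51
    axis = central_axis(m)
    length, dia = measure_branch(m, axis)
    assert length == pytest.approx(321.0, rel=0.05)
    assert dia == pytest.approx(51.0, rel=0.05)


def test_thin_rectangle_diameter():
    m = np.zeros((12, 110), bool)
    m[4:8, 5:105] = True  # 100 x 4
    axis = central_axis(m)
    _, dia = measure_branch(m, axis)
    assert dia == pytest.approx(4.0, abs=1.0)


def _tube_mask(path, radius, shape):
    """All pixels within ``radius`` of a dense polyline (smooth tube)."""
    grid = np.ones(shape, bool)
    ri = np.clip(np.round(path[:, 0]).astype(int), 0, shape[0] - 1)
    ci = np.clip(np.round(path[:, 1]).astype(int), 0, shape[1] - 1)
    grid[ri, ci] = False
    return ndimage.distance_transform_edt(grid) <= radius


def test_curved_tube_constant_diameter():
    """A bent tube of constant 10 px width keeps diameter ~10, matching an
    equally rasterized straight tube (curvature robustness)."""
    t = np.linspace(0, np.pi * 0.8, 600)
    curved_path = np.column_stack([60 + 40 * np.sin(t), 20 + 80 * t / np.pi])
    curved = _tube_mask(curved_path, 5.0, (120, 120))
    _, dia = measure_branch(curved, central_axis(curved))
    assert dia == pytest.approx(10.0, rel=0.12)

    straight_path = np.column_stack([np.linspace(15, 105, 600), np.linspace(15, 105, 600)])
    straight = _tube_mask(straight_path, 5.0, (120, 120))
    _, dia_straight = measure_branch(straight, central_axis(straight))
    assert dia == pytest.approx(dia_straight, rel=0.10)


def test_measurements_rotation_robust(table1_fixture):
    """Rotating a mask by 90 degrees changes LL/LW by under 2%."""
    mask = table1_fixture.organ_masks["leaf_1"]
    ll0, lw0 = measure_leaf(mask, central_axis(mask))
    rot = np.rot90(mask)
    ll1, lw1 = measure_leaf(rot, central_axis(rot))
    assert abs(ll1 - ll0) / ll0 < 0.02
    assert abs(lw1 - lw0) / lw0 < 0.02


def test_degenerate_axis_raises():
    with pytest.raises(ValueError):
        measure_leaf(np.ones((3, 3), bool), Axis(points=np.array([[1.0, 1.0]])))


# ---------------------------------------------------------------------------
# inclination angle


def _axis_from(p0, p1, n=50):
    return Axis(points=np.linspace(p0, p1, n))


def test_perpendicular_axes_90deg():
    branch = _axis_from([100.0, 50.0], [0.0, 50.0])  # base->apex upward
    leaf = _axis_from([50.0, 50.0], [50.0, 120.0])
    assert inclination_angle(leaf, branch) == pytest.approx(90.0, abs=1e-6)


def test_parallel_axes_0deg():
    branch = _axis_from([100.0, 50.0], [0.0, 50.0])
    leaf = _axis_from([50.0, 50.0], [-20.0, 50.0])
    assert inclination_angle(leaf, branch) == pytest.approx(0.0, abs=1e-6)


def test_detached_leaf_raises():
    branch = _axis_from([100.0, 50.0], [0.0, 50.0])
    leaf = _axis_from([50.0, 500.0], [50.0, 600.0])
    with pytest.raises(ValueError, match="not attached"):
        inclination_angle(leaf, branch)


def test_obtuse_angle_reported_beyond_90(table1_fixture):
    """A leaf drooping past perpendicular reports an angle above 90."""
    feats = extract_shoot_features(table1_fixture.organ_masks)
    second = [lf for lf in feats.leaves if lf.order == 2][0]
    assert 90.0 < second.inclination_deg <= 180.0


# ---------------------------------------------------------------------------
# full pipeline and serialization


def test_table1_recovery(table1_features, table1_fixture):
    """The reference fixture's parameters are recovered within 5% / 3 deg."""
    feats = table1_features
    tp = table1_fixture.true_params
    assert feats.branch_length == pytest.approx(tp["branch"]["length"], rel=0.05)
    assert feats.branch_diameter == pytest.approx(tp["branch"]["diameter"], rel=0.05)
    for lf in feats.leaves:
        t = tp[f"leaf_{lf.order}"]
        assert lf.length == pytest.approx(t["length"], rel=0.05)
        assert lf.width == pytest.approx(t["width"], rel=0.05)
        assert lf.inclination_deg == pytest.approx(t["inclination_deg"], abs=3.0)
    t = tp["bud"]
    assert feats.bud_length == pytest.approx(t["length"], rel=0.05)
    assert feats.bud_diameter == pytest.approx(t["width"], rel=0.05)
    assert feats.bud_angle_deg == pytest.approx(t["inclination_deg"], abs=3.0)


def test_features_json_round_trip(table1_features, tmp_path):
    path = tmp_path / "feats.json"
    table1_features.to_json(path)
    back = ShootFeatures.from_json(str(path))
    assert back.branch_length == table1_features.branch_length
    assert len(back.leaves) == len(table1_features.leaves)
    assert back.leaves[0].inclination_deg == table1_features.leaves[0].inclination_deg
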