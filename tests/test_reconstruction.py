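import numpy as np
import pytest
import trimesh

from teashoot3d.features import LeafFeatures, ShootFeatures
from teashoot3d.morphology_models import LeafWidthModel
from teashoot3d.reconstruction import (
    DEFAULT_SCHEDULE,
    GrowthSchedule,
    GrowthStage,
    LeafTemplate,
    assemble_shoot,
    boundary_loops,
    build_branch,
    build_leaf,
    export_mesh,
    match_leaf_template,
    measured_inclination,
    simulate_growth,
)


@pytest.fixture(scope="module")
def table1_model():
    feats = ShootFeatures(
        leaves=[LeafFeatures(1, 417.0, 118.0, 49.8), LeafFeatures(2, 779.0, 325.0, 131.1)],
        branch_length=321.0,
        branch_diameter=51.0,
        bud_length=298.0,
        bud_diameter=55.0,
        bud_angle_deg=75.8,
    )
    return assemble_shoot(feats)


# ---------------------------------------------------------------------------
# branch cylinders


def test_straight_cylinder_vertices_on_radius():
    skel = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 321.0]])
    bc = build_branch(skel, 25.5, 25.5, n_sides=12)
    ring = bc.mesh.vertices[:-2]  # all but the two cap centers
    d = np.linalg.norm(ring[:, :2], axis=1)
    assert np.allclose(d, 25.5)
    assert bc.mesh.is_watertight


def test_cylinder_volume_closed_form():
    n = 16
    skel = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 100.0]])
    bc = build_branch(skel, 10.0, 10.0, n_sides=n)
    polygon_correction = n * np.sin(2 * np.pi / n) / (2 * np.pi)
    assert abs(bc.mesh.volume) == pytest.approx(
        np.pi * 100.0 * 100.0 * polygon_correction, rel=1e-9
    )


def test_cone_degenerate_tip():
    skel = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 50.0]])
    bc = build_branch(skel, 10.0, 0.0, n_sides=8)
    assert bc.mesh.is_watertight
    tip_ring = bc.mesh.vertices[8:16]
    assert np.allclose(tip_ring, [0.0, 0.0, 50.0])


def test_curved_branch_watertight():
    t = np.linspace(0, 1, 12)
    skel = np.column_stack([10 * np.sin(2 * t), np.zeros_like(t), 100 * t])
    bc = build_branch(skel, 6.0, 3.0, n_sides=10)
    assert bc.mesh.is_watertight


def test_branch_rejects_bad_input():
    with pytest.raises(ValueError):
        build_branch(np.zeros((1, 3)), 1.0, 1.0)
    with pytest.raises(ValueError):
        build_branch(np.array([[0, 0, 0], [0, 0, 1.0]]), 1.0, 1.0, n_sides=2)


# ---------------------------------------------------------------------------
# leaf meshes


def _straight_vein(L=417.0, n=50):
    return np.column_stack([np.linspace(0, L, n), np.zeros(n), np.zeros(n)])


def test_leaf_triangle_count():
    wm = LeafWidthModel(a=-4, b=4, c=0, LW=118.0, LL=417.0)
    mesh = build_leaf(_straight_vein(), wm, n_edge_vertices=9)
    assert len(mesh.faces) == 2 * (9 - 1) * 2
    assert len(mesh.vertices) == 3 * 9
    assert len(mesh.uv) == len(mesh.vertices)


def test_flat_leaf_is_planar_and_area_converges():
    """With no fold and a straight vein the mesh is planar and its area
    approaches k * LW * LL with k = 2/3 for the default profile."""
    wm = LeafWidthModel(a=-4, b=4, c=0, LW=118.0, LL=417.0)
    mesh = build_leaf(
        _straight_vein(n=300), wm, n_edge_vertices=400,
        fold_angle_deg=0.0, allow_any_vertex_count=True,
    )
    assert np.allclose(mesh.vertices[:, 2], 0.0)
    assert mesh.area == pytest.approx((2.0 / 3.0) * 118.0 * 417.0, rel=1e-3)


def test_leaf_area_refines_toward_model_area():
    wm = LeafWidthModel(a=-4, b=4, c=0, LW=100.0, LL=300.0)
    target = (2.0 / 3.0) * 100.0 * 300.0
    errs = []
    for m in (8, 32, 128):
        mesh = build_leaf(
            _straight_vein(L=300.0, n=200), wm, n_edge_vertices=m,
            fold_angle_deg=0.0, allow_any_vertex_count=True,
        )
        errs.append(abs(mesh.area - target))
    assert errs[0] > errs[1] > errs[2]


def test_leaf_single_boundary_loop():
    wm = LeafWidthModel(a=-4, b=4, c=0, LW=60.0, LL=200.0)
    mesh = build_leaf(_straight_vein(L=200.0), wm, n_edge_vertices=10, fold_angle_deg=25.0)
    assert len(boundary_loops(mesh.vertices, mesh.faces)) == 1


def test_leaf_vertex_count_bounds_enforced():
    wm = LeafWidthModel(a=-4, b=4, c=0, LW=60.0, LL=200.0)
    with pytest.raises(ValueError, match="8-10"):
        build_leaf(_straight_vein(), wm, n_edge_vertices=12)
    build_leaf(_straight_vein(), wm, n_edge_vertices=12, allow_any_vertex_count=True)


def test_zero_width_leaf_warns():
    wm = LeafWidthModel.__new__(LeafWidthModel)
    object.__setattr__(wm, "a", 0.0)
    object.__setattr__(wm, "b", 0.0)
    object.__setattr__(wm, "c", 0.0)
    object.__setattr__(wm, "LW", 10.0)
    object.__setattr__(wm, "LL", 100.0)
    with pytest.warns(UserWarning, match="zero-width"):
        build_leaf(_straight_vein(L=100.0), wm, n_edge_vertices=9)


def test_fold_lifts_outline_upward():
    wm = LeafWidthModel(a=-4, b=4, c=0, LW=100.0, LL=300.0)
    mesh = build_leaf(_straight_vein(L=300.0), wm, n_edge_vertices=9, fold_angle_deg=40.0)
    m = mesh.n_edge_vertices
    outline_z = mesh.vertices[m:, 2]
    assert outline_z.max() > 1.0
    assert outline_z.min() >= -1e-9


# ---------------------------------------------------------------------------
# template matching


def test_template_exact_match_scale_one():
    db = [LeafTemplate(1, 400.0, 120.0), LeafTemplate(2, 779.0, 325.0)]
    tpl, scale = match_leaf_template((779.0, 325.0), db)
    assert tpl.id == 2
    assert scale == pytest.approx(1.0)


def test_template_nearest_by_shape():
    db = [LeafTemplate(1, 400.0, 120.0), LeafTemplate(2, 800.0, 330.0)]
    tpl, _ = match_leaf_template((779.0, 325.0), db)
    assert tpl.id == 2


def test_template_tie_breaks_on_lowest_id():
    db = [LeafTemplate(3, 100.0, 40.0), LeafTemplate(1, 100.0, 40.0), LeafTemplate(2, 100.0, 40.0)]
    tpl, _ = match_leaf_template((250.0, 100.0), db)
    assert tpl.id == 1


def test_template_empty_database_raises():
    with pytest.raises(ValueError):
        match_leaf_template((100.0, 40.0), [])


# ---------------------------------------------------------------------------
# assembly


def test_assembled_counts_and_orientations(table1_model):
    model = table1_model
    assert len(model.leaves) == 2
    assert model.bud is not None
    assert model.branch.mesh.is_watertight
    angles = {leaf.order: measured_inclination(leaf) for leaf in model.leaves}
    assert angles[1] == pytest.approx(49.8, abs=0.5)
    assert angles[2] == pytest.approx(131.1, abs=0.5)
    assert measured_inclination(model.bud) == pytest.approx(75.8, abs=0.5)


def test_leaf_attachments_on_branch_skeleton(table1_model):
    skel = table1_model.branch.skeleton
    for leaf in table1_model.leaves:
        p = leaf.attach_point
        # attachment lies on the (vertical) skeleton segment
        assert np.allclose(p[:2], skel[0][:2])
        assert skel[0][2] - 1e-9 <= p[2] <= skel[1][2] + 1e-9


def test_opposite_leaves_alternate_azimuth(table1_model):
    a = [leaf.azimuth_deg for leaf in sorted(table1_model.leaves, key=lambda l: l.order)]
    assert abs((a[1] - a[0]) % 360.0) == pytest.approx(180.0)


def test_single_leaf_minimal_model():
    feats = ShootFeatures(
        leaves=[LeafFeatures(1, 200.0, 80.0, 60.0)],
        branch_length=150.0, branch_diameter=20.0,
    )
    model = assemble_shoot(feats)
    assert len(model.leaves) == 1
    assert model.bud is None
    assert model.branch.mesh.is_watertight


def test_assemble_requires_branch():
    with pytest.raises(ValueError):
        assemble_shoot(ShootFeatures(leaves=[LeafFeatures(1, 100.0, 40.0, 50.0)]))


def test_templates_provide_texture(table1_model, tmp_path):
    db = [LeafTemplate(1, 400.0, 120.0, texture_ref="generic_leaf.png")]
    feats = table1_model.features
    model = assemble_shoot(feats, templates=db)
    assert model.leaves[0].texture_refs == ["generic_leaf.png"]
    # segmentation-derived texture overwrites the generic one
    model.leaves[0].texture_refs.append("crop_0.png")
    assert model.leaves[0].texture_ref == "crop_0.png"


# ---------------------------------------------------------------------------
# growth


def test_growth_identity_at_bud_start(table1_model):
    grown = simulate_growth(table1_model, GrowthStage("bud", 0.0))
    for a, b in zip(grown.leaves, table1_model.leaves):
        assert np.allclose(a.vertices, b.vertices)


def test_absolute_theta_schedule_interpolates():
    sched = GrowthSchedule(
        stages={
            "bud": {"LL": (1.0, 1.0), "LW": (1.0, 1.0), "theta": (20.0, 30.0), "kappa": (1.0, 1.0)},
            "expansion": {"LL": (1.0, 1.5), "LW": (1.0, 1.5), "theta": (30.0, 60.0), "kappa": (1.0, 1.0)},
            "formation": {"LL": (1.5, 1.5), "LW": (1.5, 1.6), "theta": (60.0, 60.0), "kappa": (1.0, 1.0)},
        },
        theta_absolute=True,
    )
    feats = ShootFeatures(
        leaves=[LeafFeatures(1, 200.0, 80.0, 45.0)], branch_length=150.0, branch_diameter=20.0
    )
    model = assemble_shoot(feats)
    grown = simulate_growth(model, GrowthStage("expansion", 0.5), sched)
    assert grown.features.leaves[0].inclination_deg == pytest.approx(45.0)


def test_leaf_area_nondecreasing_across_stages(table1_model):
    areas = []
    for stage in ("bud", "expansion", "formation"):
        for t in (0.0, 0.5, 1.0):
            grown = simulate_growth(table1_model, GrowthStage(stage, t))
            lf = grown.features.leaves[0]
            areas.append(lf.length * lf.width)
    assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))


def test_formation_elongation_below_one_percent(table1_model):
    l0 = simulate_growth(table1_model, GrowthStage("formation", 0.0)).features.leaves[0].length
    l1 = simulate_growth(table1_model, GrowthStage("formation", 1.0)).features.leaves[0].length
    assert abs(l1 - l0) / l0 <= 0.01


def test_non_monotone_schedule_rejected():
    bad = dict(DEFAULT_SCHEDULE.stages)
    bad["expansion"] = dict(bad["expansion"], LL=(1.5, 1.2))
    with pytest.raises(ValueError, match="non-decreasing"):
        GrowthSchedule(stages=bad)


def test_invalid_stage_rejected():
    with pytest.raises(ValueError):
        GrowthStage("seedling", 0.5)
    with pytest.raises(ValueError):
        GrowthStage("bud", 1.5)


# ---------------------------------------------------------------------------
# export


def test_obj_round_trip_vertex_count(table1_model, tmp_path):
    path = str(tmp_path / "shoot.obj")
    export_mesh(table1_model, path)
    loaded = trimesh.load(path, process=False, maintain_order=True)
    n_expected = len(table1_model.branch.mesh.vertices) + sum(
        len(l.vertices) for l in table1_model.leaves
    ) + len(table1_model.bud.vertices)
    if hasattr(loaded, "geometry"):
        n_loaded = sum(len(g.vertices) for g in loaded.geometry.values())
        n_faces = sum(len(g.faces) for g in loaded.geometry.values())
    else:
        n_loaded, n_faces = len(loaded.vertices), len(loaded.faces)
    assert n_loaded == n_expected
    n_faces_expected = len(table1_model.branch.mesh.faces) + sum(
        len(l.faces) for l in table1_model.leaves
    ) + len(table1_model.bud.faces)
    assert n_faces == n_faces_expected


def test_ply_export_parses(table1_model, tmp_path):
    path = str(tmp_path / "shoot.ply")
    export_mesh(table1_model, path)
    loaded = trimesh.load(path, process=False)
    assert len(loaded.vertices) > 0


def test_textured_export_writes_mtl(tmp_path):
    db = [LeafTemplate(1, 400.0, 120.0, texture_ref="leaf_tex.png")]
    feats = ShootFeatures(
        leaves=[LeafFeatures(1, 400.0, 120.0, 50.0)],
        branch_length=300.0, branch_diameter=40.0,
    )
    model = assemble_shoot(feats, templates=db)
    path = str(tmp_path / "tex.obj")
    export_mesh(model, path)
    mtl = tmp_path / "tex.mtl"
    assert mtl.exists()
    assert "map_Kd leaf_tex.png" in mtl.read_text()
    text = (tmp_path / "tex.obj").read_text()
    n_vt = sum(1 for l in text.splitlines() if l.startswith("vt "))
    assert n_vt == len(model.leaves[0].uv)


def test_export_rejects_unknown_format(table1_model, tmp_path):
    with pytest.raises(ValueError):
        export_mesh(table1_model, str(tmp_path / "shoot.stl"))
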