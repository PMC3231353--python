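"""Parametric 3D reconstruction of a tea shoot and its staged growth.

The assembled model places the shoot in a world frame with ``z`` up and the
branch base at the origin:

* **branches** are generalized cylinders — an ``n_sides`` polygon swept
  along a 3D skeleton polyline with the radius linearly interpolated
  between the two end radii, closed with end caps (watertight);
* **leaves** are thin triangulated surfaces: the vein polyline comes from
  the cantilever bending model, the outline from the quadratic width
  profile placed perpendicular to the vein and folded upward about it by a
  small angle; each outline side carries 8-10 vertices and the vein's head
  and tail coincide with the outline endpoints;
* the **bud** is a narrow leaf variant at the branch apex.

Image-measured parameters are planar; the third dimension is supplied by
the parametric lift — the cantilever sag bends the vein out of the leaf
insertion direction, and the fold angle lifts the lamina out of the vein's
bending plane.  Growth is simulated by re-assembling the model with
stage-dependent multipliers on leaf length, width, inclination and bending.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .features import LeafFeatures, ShootFeatures
from .morphology_models import (
    DEFAULT_WIDTH_COEFFS,
    LeafWidthModel,
    VeinCurveParams,
    vein_curve,
)
from .synthetic_data import kappa_for_sag

__all__ = [
    "BranchCylinder",
    "LeafMesh",
    "LeafTemplate",
    "ShootModel",
    "GrowthStage",
    "GrowthSchedule",
    "DEFAULT_SCHEDULE",
    "build_branch",
    "build_leaf",
    "match_leaf_template",
    "assemble_shoot",
    "simulate_growth",
    "export_mesh",
    "boundary_loops",
    "mesh_surface_area",
]


# ---------------------------------------------------------------------------
# data types


@dataclass
class BranchCylinder:
    """Generalized-cylinder branch: swept polygon with interpolated radius."""

    skeleton: np.ndarray  # (n, 3) polyline
    radius_start: float
    radius_end: float
    n_sides: int
    mesh: trimesh.Trimesh


@dataclass
class LeafMesh:
    """Triangulated leaf surface.

    ``vertices`` holds the ``m`` vein stations followed by ``m`` left and
    ``m`` right outline vertices (``m = n_edge_vertices``); ``vein3d`` is
    the dense vein polyline the stations were sampled from.  ``uv`` maps
    the vein to ``v = 0.5`` with the outline spreading toward 0 and 1.
    ``texture_refs`` is a two-slot list: the generic template texture
    first, overwritten by a segmented-image crop when one is available.
    """

    vertices: np.ndarray  # (3m, 3)
    faces: np.ndarray  # (4(m-1), 3)
    uv: np.ndarray  # (3m, 2)
    vein3d: np.ndarray  # dense (k, 3) polyline
    n_edge_vertices: int
    attach_point: np.ndarray | None = None
    order: int | None = None
    inclination_deg: float | None = None
    azimuth_deg: float | None = None
    texture_refs: list = field(default_factory=list)

    @property
    def area(self) -> float:
        v = self.vertices
        tri = v[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    @property
    def texture_ref(self):
        """Active texture: the last (most specific) reference, if any."""
        return self.texture_refs[-1] if self.texture_refs else None


@dataclass(frozen=True)
class LeafTemplate:
    """Database entry: a sample leaf with its dimensions and texture."""

    id: int
    LL: float
    LW: float
    outline: np.ndarray | None = None
    texture_ref: str | None = None


@dataclass
class ShootModel:
    """Assembled 3D shoot plus the parameters needed to rebuild it."""

    branch: BranchCylinder
    leaves: list  # LeafMesh
    bud: LeafMesh | None
    features: ShootFeatures
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# mesh construction


def _parallel_transport_frames(skeleton: np.ndarray):
    pts = np.asarray(skeleton, dtype=np.float64)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t0 @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = ref - (ref @ t0) * t0
    n /= np.linalg.norm(n)
    normals = [n]
    for i in range(1, len(pts)):
        t_prev, t_cur = tangents[i - 1], tangents[i]
        v = np.cross(t_prev, t_cur)
        s = np.linalg.norm(v)
        c = float(np.clip(t_prev @ t_cur, -1.0, 1.0))
        if s < 1e-12:
            normals.append(normals[-1])
            continue
        axis = v / s
        ang = np.arctan2(s, c)
        normals.append(_rotate_about(normals[-1], axis, ang))
    normals = np.array(normals)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of vector(s) v about a unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ np.atleast_2d(v).T).T.squeeze() * (1 - c)


def build_branch(
    skeleton: np.ndarray, r0: float, r1: float, n_sides: int = 16
) -> BranchCylinder:
    """Sweep an ``n_sides`` polygon along a skeleton into a capped cylinder.

    The radius varies linearly with arc length from ``r0`` to ``r1``; the
    result is watertight.  A warning is emitted if consecutive skeleton
    points are closer than the local radius (self-intersection risk).
    """
    pts = np.asarray(skeleton, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("skeleton must be an (n>=2, 3) polyline")
    if r0 <= 0 or r1 < 0:
        raise ValueError("radii must be positive (end radius may be 0 for a cone tip)")
    if n_sides < 3:
        raise ValueError("n_sides must be >= 3")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("skeleton contains repeated points")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    radii = r0 + (r1 - r0) * arc / arc[-1]
    if len(pts) > 2 and np.any(seg < 0.5 * radii[:-1]):
        warnings.warn("skeleton turns tighter than the local radius; the sweep may self-intersect", stacklevel=2)

    tangents, normals, binormals = _parallel_transport_frames(pts)
    S = n_sides
    theta = 2 * np.pi * np.arange(S) / S
    rings = (
        pts[:, None, :]
        + radii[:, None, None]
        * (np.cos(theta)[None, :, None] * normals[:, None, :]
           + np.sin(theta)[None, :, None] * binormals[:, None, :])
    )
    verts = rings.reshape(-1, 3)
    faces = []
    n = len(pts)
    for i in range(n - 1):
        for k in range(S):
            a = i * S + k
            b = i * S + (k + 1) % S
            c = (i + 1) * S + (k + 1) % S
            d = (i + 1) * S + k
            faces.append((a, b, c))
            faces.append((a, c, d))
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.vstack([verts, pts[0], pts[-1]])
    for k in range(S):
        faces.append((c0, (k + 1) % S, k))  # base cap, inward-facing start
        faces.append((c1, (n - 1) * S + k, (n - 1) * S + (k + 1) % S))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    return BranchCylinder(
        skeleton=pts, radius_start=float(r0), radius_end=float(r1),
        n_sides=n_sides, mesh=mesh,
    )


def _resample3d(points: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=np.float64)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, arc[-1], n)
    out = np.column_stack([np.interp(t, arc, pts[:, d]) for d in range(3)])
    return out, t / max(arc[-1], 1e-12)


def build_leaf(
    vein3d: np.ndarray,
    width_model: LeafWidthModel,
    n_edge_vertices: int = 9,
    fold_angle_deg: float = 20.0,
    allow_any_vertex_count: bool = False,
) -> LeafMesh:
    """Triangulate a leaf surface around a 3D vein polyline.

    ``n_edge_vertices`` stations are sampled along the vein; at each, the
    outline points sit at half the local width on either side,
    perpendicular to the vein tangent, rotated upward about the vein by
    half the fold angle.  Triangles fan between consecutive vein and
    outline points (``2 * (m - 1)`` per side).  Outline endpoints coincide
    with the vein head and tail, so the mesh has a single boundary loop.
    """
    m = int(n_edge_vertices)
    if not allow_any_vertex_count and not 8 <= m <= 10:
        raise ValueError(
            "n_edge_vertices must be 8-10 (pass allow_any_vertex_count=True to override)"
        )
    if m < 3:
        raise ValueError("need at least 3 edge vertices")
    vein_dense = np.asarray(vein3d, dtype=np.float64)
    if vein_dense.ndim != 2 or vein_dense.shape[0] < 2 or vein_dense.shape[1] != 3:
        raise ValueError("vein3d must be an (n>=2, 3) polyline")
    stations, s = _resample3d(vein_dense, m)

    tan = np.gradient(stations, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    up = np.array([0.0, 0.0, 1.0])
    side = np.cross(tan, up)
    nrm = np.linalg.norm(side, axis=1, keepdims=True)
    # vertical tangent: fall back to the x axis for the lamina direction
    bad = nrm[:, 0] < 1e-9
    side[bad] = np.array([1.0, 0.0, 0.0])
    nrm[bad] = 1.0
    side /= np.linalg.norm(side, axis=1, keepdims=True)

    prof = width_model.a * s**2 + width_model.b * s + width_model.c
    half = 0.5 * width_model.LW * np.maximum(prof, 0.0)
    if half.max() <= 1e-9:
        warnings.warn("zero-width profile: leaf mesh degenerates to a strip", stacklevel=2)

    fold = np.radians(fold_angle_deg) / 2.0
    left = np.empty_like(stations)
    right = np.empty_like(stations)
    for i in range(m):
        # rotate both outline directions so the lamina folds upward
        dl = _rotate_about(side[i], tan[i], -fold)
        dr = _rotate_about(-side[i], tan[i], fold)
        left[i] = stations[i] + half[i] * dl
        right[i] = stations[i] + half[i] * dr

    verts = np.vstack([stations, left, right])
    uv_prof = np.clip(prof, 0.0, None) / 2.0
    uv = np.vstack(
        [
            np.column_stack([s, np.full(m, 0.5)]),
            np.column_stack([s, 0.5 + uv_prof]),
            np.column_stack([s, 0.5 - uv_prof]),
        ]
    )
    faces = []
    L = lambda i: m + i
    R = lambda i: 2 * m + i
    for i in range(m - 1):
        faces.append((i, L(i + 1), L(i)))
        faces.append((i, i + 1, L(i + 1)))
        faces.append((i, R(i), R(i + 1)))
        faces.append((i, R(i + 1), i + 1))
    return LeafMesh(
        vertices=verts,
        faces=np.array(faces),
        uv=uv,
        vein3d=vein_dense,
        n_edge_vertices=m,
    )


def boundary_loops(vertices: np.ndarray, faces: np.ndarray) -> list:
    """Closed loops of boundary edges (edges used by exactly one face)."""
    edges: dict[tuple[int, int], int] = {}
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edges[key] = edges.get(key, 0) + 1
    boundary = [e for e, c in edges.items() if c == 1]
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    loops = []
    unused = set(boundary)
    while unused:
        a, b = next(iter(unused))
        loop = [a, b]
        unused.discard((min(a, b), max(a, b)))
        while True:
            cur, prev = loop[-1], loop[-2]
            nxts = [v for v in adj[cur] if v != prev and (min(cur, v), max(cur, v)) in unused]
            if not nxts:
                break
            nxt = nxts[0]
            unused.discard((min(cur, nxt), max(cur, nxt)))
            if nxt == loop[0]:
                break
            loop.append(nxt)
        loops.append(loop)
    return loops


def mesh_surface_area(mesh: LeafMesh) -> float:
    return mesh.area


# ---------------------------------------------------------------------------
# template matching


def match_leaf_template(
    query: tuple[float, float] | LeafFeatures, templates: list
) -> tuple[LeafTemplate, float]:
    """Pick the database leaf most similar in length and width.

    For each template the optimal uniform scale minimizing
    ``(s*LL_t - LL_q)^2 + (s*LW_t - LW_q)^2`` is applied, and the template
    with the smallest normalized residual wins; ties break on the lowest
    template id.  Returns ``(template, scale)``.
    """
    if not templates:
        raise ValueError("template database is empty")
    if isinstance(query, LeafFeatures):
        llq, lwq = query.length, query.width
    else:
        llq, lwq = query
    norm = llq**2 + lwq**2
    best = None
    for t in sorted(templates, key=lambda t: t.id):
        denom = t.LL**2 + t.LW**2
        s = (t.LL * llq + t.LW * lwq) / denom
        resid = ((s * t.LL - llq) ** 2 + (s * t.LW - lwq) ** 2) / norm
        if best is None or resid < best[0] - 1e-15:
            best = (resid, t, s)
    return best[1], float(best[2])


# ---------------------------------------------------------------------------
# assembly


def _attach_fraction(order: int) -> float:
    """Leaf insertion height along the branch: leaf order 1 sits nearest
    the apex and successive leaves step down (mirrors the generator)."""
    return max(0.2, 0.8 - 0.3 * (order - 1))


def _leaf_vein_3d(
    attach: np.ndarray, length: float, theta_deg: float, azimuth_deg: float,
    kappa: float, n: int = 96,
) -> np.ndarray:
    """Lift the planar cantilever curve into the world frame.

    The curve lives in the vertical plane of azimuth ``phi``: its along-
    stem coordinate maps to +z (the branch direction), its lateral
    coordinate to the horizontal unit vector of ``phi``, and sag maps to
    -z, so the vein leaves the branch at ``theta`` from vertical and bends
    downward.
    """
    params = VeinCurveParams(L=length, theta=theta_deg, kappa=kappa)
    c = vein_curve(params, n_samples=n)
    phi = np.radians(azimuth_deg)
    u1 = np.array([np.cos(phi), np.sin(phi), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    return attach[None, :] + c[:, 0:1] * u1[None, :] - c[:, 1:2] * z[None, :]


def assemble_shoot(
    features: ShootFeatures,
    width_coeffs: tuple = DEFAULT_WIDTH_COEFFS,
    templates: list | None = None,
    n_sides: int = 16,
    n_edge_vertices: int = 9,
    fold_angle_deg: float = 20.0,
    sag_frac: float = 0.04,
    azimuth0_deg: float = 0.0,
) -> ShootModel:
    """Assemble the full 3D shoot from measured features.

    The branch is a vertical generalized cylinder of the measured length
    and diameter; leaves attach in leaf order along it, oriented at their
    measured inclination angles with azimuths alternating by 180 degrees
    (opposite insertion); the bud sits at the apex.  When a template
    database is supplied each leaf inherits the texture of its best match.
    """
    if features.branch_length <= 0 or features.branch_diameter <= 0:
        raise ValueError("features must include positive branch length and diameter")
    if not features.leaves and features.bud_length <= 0:
        raise ValueError("features must include at least one leaf or a bud")
    L = features.branch_length
    r = features.branch_diameter / 2.0
    skeleton = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, L]])
    branch = build_branch(skeleton, r, r, n_sides=n_sides)

    a, b, c = width_coeffs
    leaves = []
    for idx, lf in enumerate(sorted(features.leaves, key=lambda x: x.order)):
        az = azimuth0_deg + 180.0 * idx
        attach = np.array([0.0, 0.0, _attach_fraction(lf.order) * L])
        kappa = kappa_for_sag(lf.length, lf.inclination_deg, sag_frac)
        vein = _leaf_vein_3d(attach, lf.length, lf.inclination_deg, az, kappa)
        arc = float(np.sum(np.linalg.norm(np.diff(vein, axis=0), axis=1)))
        wm = LeafWidthModel(a=a, b=b, c=c, LW=lf.width, LL=arc)
        mesh = build_leaf(vein, wm, n_edge_vertices=n_edge_vertices, fold_angle_deg=fold_angle_deg)
        mesh.attach_point = attach
        mesh.order = lf.order
        mesh.inclination_deg = lf.inclination_deg
        mesh.azimuth_deg = az
        if templates:
            tpl, _scale = match_leaf_template((lf.length, lf.width), templates)
            if tpl.texture_ref:
                mesh.texture_refs.append(tpl.texture_ref)
        leaves.append(mesh)

    bud = None
    if features.bud_length > 0:
        az = azimuth0_deg + 180.0 * len(leaves)
        attach = np.array([0.0, 0.0, L])
        kappa = kappa_for_sag(features.bud_length, features.bud_angle_deg, 0.02)
        vein = _leaf_vein_3d(attach, features.bud_length, features.bud_angle_deg, az, kappa)
        arc = float(np.sum(np.linalg.norm(np.diff(vein, axis=0), axis=1)))
        wm = LeafWidthModel(a=a, b=b, c=c, LW=features.bud_diameter, LL=arc)
        # the bud is horn-shaped: a tight fold along the vein
        bud = build_leaf(vein, wm, n_edge_vertices=n_edge_vertices, fold_angle_deg=100.0)
        bud.attach_point = attach
        bud.inclination_deg = features.bud_angle_deg
        bud.azimuth_deg = az

    return ShootModel(
        branch=branch,
        leaves=leaves,
        bud=bud,
        features=features,
        config={
            "width_coeffs": tuple(width_coeffs),
            "n_sides": n_sides,
            "n_edge_vertices": n_edge_vertices,
            "fold_angle_deg": fold_angle_deg,
            "sag_frac": sag_frac,
            "azimuth0_deg": azimuth0_deg,
            "templates": templates,
        },
    )


def measured_inclination(mesh: LeafMesh, branch_dir=np.array([0.0, 0.0, 1.0])) -> float:
    """Angle between a leaf's base tangent and the branch direction, from
    the assembled geometry (degrees)."""
    d = mesh.vein3d[1] - mesh.vein3d[0]
    d = d / np.linalg.norm(d)
    return float(np.degrees(np.arccos(np.clip(d @ branch_dir, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# growth simulation


@dataclass(frozen=True)
class GrowthStage:
    """One point of the three-stage leaf formation: ``bud`` (curved,
    horn-shaped), ``expansion`` (the stem-leaf angle opens, the lamina
    spreads), ``formation`` (elongation essentially stops)."""

    stage: str
    t: float

    def __post_init__(self):
        if self.stage not in ("bud", "expansion", "formation"):
            raise ValueError("stage must be 'bud', 'expansion' or 'formation'")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")


_STAGE_ORDER = ("bud", "expansion", "formation")


@dataclass(frozen=True)
class GrowthSchedule:
    """Per-stage multiplier ranges on the leaf parameters.

    ``stages[stage][param] = (m_start, m_end)``: the multiplier applied at
    ``t`` within a stage interpolates linearly.  ``theta_absolute`` makes
    the ``theta`` entries absolute angles in degrees instead of
    multipliers.  Length and width multipliers must be non-decreasing
    across the bud -> expansion -> formation sequence, and length may
    change by at most 1% within formation (elongation has stopped).
    """

    stages: dict = field(default_factory=lambda: {
        "bud": {"LL": (1.0, 1.5), "LW": (1.0, 1.4), "theta": (1.0, 1.1), "kappa": (1.0, 1.2)},
        "expansion": {"LL": (1.5, 2.2), "LW": (1.4, 2.2), "theta": (1.1, 1.35), "kappa": (1.2, 1.0)},
        "formation": {"LL": (2.2, 2.2), "LW": (2.2, 2.35), "theta": (1.35, 1.4), "kappa": (1.0, 1.0)},
    })
    theta_absolute: bool = False

    def __post_init__(self):
        for param in ("LL", "LW"):
            seq = []
            for st in _STAGE_ORDER:
                m0, m1 = self.stages[st][param]
                seq.extend([m0, m1])
            if any(b < a - 1e-12 for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{param} schedule is not non-decreasing across stages")
        f0, f1 = self.stages["formation"]["LL"]
        if abs(f1 - f0) > 0.01 * f0:
            raise ValueError("leaf length may change by at most 1% within the formation stage")

    def multiplier(self, stage: str, t: float, param: str) -> float:
        m0, m1 = self.stages[stage][param]
        return m0 + (m1 - m0) * t


DEFAULT_SCHEDULE = GrowthSchedule()


def simulate_growth(
    model: ShootModel, stage: GrowthStage, schedule: GrowthSchedule = DEFAULT_SCHEDULE
) -> ShootModel:
    """Re-assemble the shoot with the stage's parameter multipliers applied.

    The input model is treated as the state at the start of the bud stage,
    so ``simulate_growth(model, GrowthStage('bud', 0))`` (with the default
    schedule, whose bud-stage multipliers start at 1) reproduces it.
    Branch dimensions are held constant; leaf and bud length, width,
    inclination and bending evolve.
    """
    mult = lambda p: schedule.multiplier(stage.stage, stage.t, p)

    def scaled_theta(theta0: float) -> float:
        if schedule.theta_absolute:
            m0, m1 = schedule.stages[stage.stage]["theta"]
            return m0 + (m1 - m0) * stage.t
        return min(theta0 * mult("theta"), 179.0)

    feats = model.features
    new_leaves = [
        LeafFeatures(
            order=lf.order,
            length=lf.length * mult("LL"),
            width=lf.width * mult("LW"),
            inclination_deg=scaled_theta(lf.inclination_deg),
        )
        for lf in feats.leaves
    ]
    new_feats = ShootFeatures(
        leaves=new_leaves,
        branch_length=feats.branch_length,
        branch_diameter=feats.branch_diameter,
        bud_length=feats.bud_length * mult("LL"),
        bud_diameter=feats.bud_diameter * mult("LW"),
        bud_angle_deg=scaled_theta(feats.bud_angle_deg),
    )
    cfg = dict(model.config)
    sag = cfg.pop("sag_frac", 0.04) * mult("kappa")
    templates = cfg.pop("templates", None)
    return assemble_shoot(
        new_feats,
        width_coeffs=cfg.pop("width_coeffs", DEFAULT_WIDTH_COEFFS),
        templates=templates,
        n_sides=cfg.pop("n_sides", 16),
        n_edge_vertices=cfg.pop("n_edge_vertices", 9),
        fold_angle_deg=cfg.pop("fold_angle_deg", 20.0),
        sag_frac=sag,
        azimuth0_deg=cfg.pop("azimuth0_deg", 0.0),
    )


# ---------------------------------------------------------------------------
# export


def _write_obj(model: ShootModel, path: str) -> None:
    mtl_path = os.path.splitext(path)[0] + ".mtl"
    materials: dict[str, str] = {}
    parts = [("branch", model.branch.mesh.vertices, model.branch.mesh.faces, None, None)]
    for leaf in model.leaves:
        parts.append((f"leaf_{leaf.order}", leaf.vertices, leaf.faces, leaf.uv, leaf.texture_ref))
    if model.bud is not None:
        parts.append(("bud", model.bud.vertices, model.bud.faces, model.bud.uv, model.bud.texture_ref))

    lines = ["# teashoot3d shoot model"]
    if any(p[4] for p in parts):
        lines.append(f"mtllib {os.path.basename(mtl_path)}")
    v_off = 1
    vt_off = 1
    for name, verts, faces, uv, tex in parts:
        lines.append(f"g {name}")
        if tex:
            mat = f"mat_{name}"
            materials[mat] = tex
            lines.append(f"usemtl {mat}")
        for v in verts:
            lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
        if uv is not None:
            for t in uv:
                lines.append(f"vt {t[0]:.6f} {t[1]:.6f}")
        for f in faces:
            if uv is not None:
                lines.append(
                    "f " + " ".join(f"{v_off + i}/{vt_off + i}" for i in f)
                )
            else:
                lines.append("f " + " ".join(str(v_off + i) for i in f))
        v_off += len(verts)
        if uv is not None:
            vt_off += len(uv)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if materials:
        with open(mtl_path, "w") as fh:
            for mat, tex in materials.items():
                fh.write(f"newmtl {mat}\nKd 0.8 0.8 0.8\nmap_Kd {tex}\n")


def export_mesh(model: ShootModel, path: str) -> str:
    """Export the assembled shoot as Wavefront OBJ (+MTL) or ASCII PLY.

    The format follows the file extension (``.obj`` or ``.ply``);
    coordinates are written with 1e-6 precision.  Returns the path.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        _write_obj(model, path)
    elif ext == ".ply":
        meshes = [model.branch.mesh]
        for leaf in model.leaves:
            meshes.append(trimesh.Trimesh(vertices=leaf.vertices, faces=leaf.faces, process=False))
        if model.bud is not None:
            meshes.append(trimesh.Trimesh(vertices=model.bud.vertices, faces=model.bud.faces, process=False))
        combined = trimesh.util.concatenate(meshes)
        combined.export(path, encoding="ascii")
    else:
        raise ValueError(f"unsupported mesh format {ext!r} (use .obj or .ply)")
    return path
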