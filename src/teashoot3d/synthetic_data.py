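"""Synthetic pseudo-photographs of tea shoots with exact ground truth.

Real tea-field photographs pair a light yellow-green shoot (terminal bud
plus tender leaves) and a darker brown branch against a background of dark
mature leaves.  This module renders that scene from the same parametric
morphology used by the reconstruction code — cantilever vein curves and
quadratic width profiles — so that every downstream module (segmentation,
feature measurement, reconstruction) can be tested against known masks and
known geometry without any photograph.

Rendering is deterministic given the spec's seed.  Rasterization is
hard-edged (no anti-aliasing) by default so the ground-truth label map is
exact; hue/saturation jitter and Gaussian blur can be added to emulate
field conditions.

What the generator does *not* emulate: lighting gradients, shadows,
specular highlights, serrated leaf margins, occlusion by foreign objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .color_space import hsi_to_rgb
from .morphology_models import (
    DEFAULT_WIDTH_COEFFS,
    LeafWidthModel,
    VeinCurveParams,
    vein_curve,
)

__all__ = [
    "LeafSpec",
    "FixtureSpec",
    "Fixture",
    "render_fixture",
    "fixture_suite",
    "table1_spec",
    "kappa_for_sag",
]

#: Label ids in the ground-truth label map.
BACKGROUND_LABEL = 1
BRANCH_LABEL = 2


def kappa_for_sag(L: float, theta_deg: float, sag_frac: float) -> float:
    """Bending coefficient giving a tip sag of ``sag_frac * L``.

    The cantilever tip deflection is ``kappa * sin(theta) * L^4 / 8``;
    solving for kappa yields the value that drops the tip by the requested
    fraction of the vein length.
    """
    st = np.sin(np.radians(theta_deg))
    if st <= 0:
        return 0.0
    return 8.0 * sag_frac / (st * L**3)


@dataclass(frozen=True)
class LeafSpec:
    """Geometry of one rendered leaf (pixel units, degrees)."""

    order: int
    length: float  # vein length L
    width: float  # maximum width LW
    theta_deg: float  # inclination from the branch axis
    side: int = 1  # +1 / -1: which side of the branch
    attach_frac: float = 0.8  # attachment height as fraction of branch length
    sag_frac: float = 0.04  # cantilever tip sag as fraction of length
    width_coeffs: tuple = DEFAULT_WIDTH_COEFFS


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of one synthetic shoot photograph."""

    rng_seed: int = 0
    branch_length: float = 321.0
    branch_diameter: float = 51.0
    bud_length: float = 298.0
    bud_diameter: float = 55.0
    bud_angle_deg: float = 75.8
    bud_side: int = 1
    leaves: tuple = (
        LeafSpec(order=1, length=417.0, width=118.0, theta_deg=49.8, side=1, attach_frac=0.8),
        LeafSpec(order=2, length=779.0, width=325.0, theta_deg=131.1, side=-1, attach_frac=0.5),
    )
    # class colors as (hue degrees, saturation, intensity); hue windows are
    # kept >= 20 degrees apart so quantization separates the classes
    shoot_hsi: tuple = (75.0, 0.55, 0.60)
    branch_hsi: tuple = (35.0, 0.50, 0.35)
    background_hsi: tuple = (145.0, 0.60, 0.30)
    shoot_hue_window: tuple = (55.0, 95.0)
    n_background_blobs: int = 5
    noise_sigma_h: float = 0.0  # hue jitter, degrees
    noise_sigma_s: float = 0.0  # saturation jitter
    blur_sigma: float = 0.0  # Gaussian blur, pixels
    two_class: bool = False  # paint the branch in the shoot color
    canvas: tuple | None = None  # (height, width); None = auto-fit
    margin: int = 16


@dataclass
class Fixture:
    """Rendered image plus exact ground truth."""

    image: np.ndarray  # (H, W, 3) RGB in [0, 1]
    label_map: np.ndarray  # visible (z-ordered) organ labels
    shoot_mask: np.ndarray  # visible shoot-class pixels
    organ_masks: dict  # organ name -> full (un-occluded) boolean mask
    true_veins: dict  # organ name -> (n, 2) polyline, (row, col)
    true_params: dict  # organ name -> dict of ground-truth measurements
    spec: FixtureSpec


def _leaf_polygon(vein_xy: np.ndarray, LW: float, coeffs: tuple) -> np.ndarray:
    """Outline polygon of a leaf around its vein polyline (leaf frame)."""
    seg = np.linalg.norm(np.diff(vein_xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    model = LeafWidthModel(a=coeffs[0], b=coeffs[1], c=coeffs[2], LW=LW, LL=max(total, 1e-9))
    s = arc / max(total, 1e-9)
    half = 0.5 * LW * np.maximum(model.a * s**2 + model.b * s + model.c, 0.0)
    tan = np.gradient(vein_xy, axis=0)
    nrm = np.linalg.norm(tan, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    tan = tan / nrm
    normal = np.column_stack([-tan[:, 1], tan[:, 0]])
    left = vein_xy + normal * half[:, None]
    right = vein_xy - normal * half[:, None]
    return np.vstack([left, right[::-1]])


def _build_geometry(spec: FixtureSpec):
    """World-frame (x right, y down, branch base at origin, apex at -y)
    polygons and vein polylines for every organ."""
    organs = []  # (name, label, polygon, vein, truth)
    hw = spec.branch_diameter / 2.0
    base = np.array([0.0, 0.0])
    tip = np.array([0.0, -spec.branch_length])
    branch_poly = np.array(
        [
            [base[0] - hw, base[1]],
            [tip[0] - hw, tip[1]],
            [tip[0] + hw, tip[1]],
            [base[0] + hw, base[1]],
        ]
    )
    branch_vein = np.vstack([base, tip])
    organs.append(
        (
            "branch",
            BRANCH_LABEL,
            branch_poly,
            branch_vein,
            {"length": spec.branch_length, "diameter": spec.branch_diameter},
        )
    )

    def leaf_geometry(L, W, theta, side, sag_frac, coeffs, attach):
        params = VeinCurveParams(
            L=L, theta=theta, kappa=kappa_for_sag(L, theta, sag_frac)
        )
        vein = vein_curve(params, n_samples=96)
        vein = vein * np.array([side, 1.0]) + attach
        poly = _leaf_polygon(vein, W, coeffs)
        seg = np.linalg.norm(np.diff(vein, axis=0), axis=1)
        return vein, poly, float(seg.sum())

    label = BRANCH_LABEL
    for leaf in sorted(spec.leaves, key=lambda lf: lf.order):
        label += 1
        attach = np.array([0.0, -leaf.attach_frac * spec.branch_length])
        vein, poly, arclen = leaf_geometry(
            leaf.length, leaf.width, leaf.theta_deg, leaf.side,
            leaf.sag_frac, leaf.width_coeffs, attach,
        )
        organs.append(
            (
                f"leaf_{leaf.order}",
                label,
                poly,
                vein,
                {
                    "length": arclen,
                    "width": leaf.width,
                    "inclination_deg": leaf.theta_deg,
                },
            )
        )

    label += 1
    vein, poly, arclen = leaf_geometry(
        spec.bud_length, spec.bud_diameter, spec.bud_angle_deg, spec.bud_side,
        0.02, DEFAULT_WIDTH_COEFFS, tip,
    )
    organs.append(
        (
            "bud",
            label,
            poly,
            vein,
            {
                "length": arclen,
                "width": spec.bud_diameter,
                "inclination_deg": spec.bud_angle_deg,
            },
        )
    )
    return organs


def render_fixture(spec: FixtureSpec) -> Fixture:
    """Rasterize a :class:`FixtureSpec` into an image plus ground truth.

    Deterministic for a given ``spec.rng_seed``.  Raises ``ValueError``
    when a fixed canvas is requested and an organ does not fit.
    """
    rng = np.random.default_rng(spec.rng_seed)
    organs = _build_geometry(spec)

    all_pts = np.vstack([poly for _, _, poly, _, _ in organs])
    lo = np.floor(all_pts.min(axis=0)) - spec.margin
    hi = np.ceil(all_pts.max(axis=0)) + spec.margin
    if spec.canvas is None:
        height = int(hi[1] - lo[1])
        width = int(hi[0] - lo[0])
        offset = -lo  # world -> canvas: col = x + offset_x, row = y + offset_y
    else:
        height, width = spec.canvas
        offset = np.array(
            [width / 2.0 - (lo[0] + hi[0]) / 2.0, height / 2.0 - (lo[1] + hi[1]) / 2.0]
        )
        for name, _, poly, _, _ in organs:
            p = poly + offset
            if p[:, 0].min() < 0 or p[:, 1].min() < 0 or p[:, 0].max() >= width or p[:, 1].max() >= height:
                raise ValueError(f"organ {name!r} does not fit the {height}x{width} canvas")

    def to_rc(xy: np.ndarray) -> np.ndarray:
        return np.column_stack([xy[:, 1] + offset[1], xy[:, 0] + offset[0]])

    label_map = np.full((height, width), BACKGROUND_LABEL, dtype=np.int64)
    hue = np.full((height, width), spec.background_hsi[0], dtype=np.float64)
    sat = np.full((height, width), spec.background_hsi[1], dtype=np.float64)
    inten = np.full((height, width), spec.background_hsi[2], dtype=np.float64)

    # mature-leaf background blobs: elliptical patches with hue variation
    # inside the background window (absent in two-class mode)
    if not spec.two_class:
        for _ in range(spec.n_background_blobs):
            cy = rng.uniform(0, height)
            cx = rng.uniform(0, width)
            ay = rng.uniform(0.12, 0.3) * height
            ax = rng.uniform(0.12, 0.3) * width
            ang = rng.uniform(0, np.pi)
            t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
            ex = ax * np.cos(t) * np.cos(ang) - ay * np.sin(t) * np.sin(ang) + cx
            ey = ax * np.cos(t) * np.sin(ang) + ay * np.sin(t) * np.cos(ang) + cy
            rr, cc = draw_polygon(ey, ex, shape=(height, width))
            dh = rng.uniform(-8.0, 8.0)
            di = rng.uniform(-0.05, 0.05)
            hue[rr, cc] = spec.background_hsi[0] + dh
            inten[rr, cc] = np.clip(spec.background_hsi[2] + di, 0.0, 1.0)

    organ_masks: dict[str, np.ndarray] = {}
    true_veins: dict[str, np.ndarray] = {}
    true_params: dict[str, dict] = {}
    for name, label, poly, vein, truth in organs:
        rc = to_rc(poly)
        rr, cc = draw_polygon(rc[:, 0], rc[:, 1], shape=(height, width))
        mask = np.zeros((height, width), dtype=bool)
        mask[rr, cc] = True
        organ_masks[name] = mask
        true_veins[name] = to_rc(vein)
        true_params[name] = truth
        label_map[mask] = label
        if name == "branch" and not spec.two_class:
            h0, s0, i0 = spec.branch_hsi
        else:
            h0, s0, i0 = spec.shoot_hsi
        hue[mask] = h0
        sat[mask] = s0
        inten[mask] = i0

    shoot_labels = {
        label for name, label, *_ in organs if name != "branch" or spec.two_class
    }
    shoot_mask = np.isin(label_map, list(shoot_labels))

    if spec.noise_sigma_h > 0:
        hue = hue + rng.normal(0.0, spec.noise_sigma_h, hue.shape)
    if spec.noise_sigma_s > 0:
        sat = np.clip(sat + rng.normal(0.0, spec.noise_sigma_s, sat.shape), 0.0, 1.0)

    hsi = np.stack([hue % 360.0, sat, inten], axis=-1)
    image = hsi_to_rgb(hsi)
    if spec.blur_sigma > 0:
        image = np.stack(
            [ndimage.gaussian_filter(image[..., k], spec.blur_sigma) for k in range(3)],
            axis=-1,
        )

    return Fixture(
        image=image,
        label_map=label_map,
        shoot_mask=shoot_mask,
        organ_masks=organ_masks,
        true_veins=true_veins,
        true_params=true_params,
        spec=spec,
    )


def table1_spec(**overrides) -> FixtureSpec:
    """The reference fixture: the measured shoot of the original experiment
    (leaf 417x118 @49.8deg, leaf 779x325 @131.1deg, branch 321x51,
    bud 298x55 @75.8deg, pixel units)."""
    return replace(FixtureSpec(), **overrides)


def fixture_suite(n: int, seed: int = 0) -> list[FixtureSpec]:
    """Randomized fixture population for parameter-recovery statistics.

    Parameters are drawn uniformly from ranges mirroring the magnitudes of
    the reference shoot: leaf length 200-800 px, width 80-350 px (capped at
    0.55x the length so leaves stay leaf-shaped), inclination 30-140 deg,
    branch 250-450 x 30-60 px, bud 150-300 x 40-60 px at 50-90 deg.
    Reproducible: each spec's seed derives from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        sub = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub)
        leaves = []
        for order, attach in ((1, 0.8), (2, 0.5)):
            ll = float(rng.uniform(200.0, 800.0))
            lw = float(rng.uniform(80.0, min(350.0, 0.55 * ll)))
            theta = float(rng.uniform(30.0, 140.0))
            side = 1 if order % 2 == 1 else -1
            leaves.append(
                LeafSpec(
                    order=order, length=ll, width=lw, theta_deg=theta,
                    side=side, attach_frac=attach,
                )
            )
        specs.append(
            FixtureSpec(
                rng_seed=sub,
                branch_length=float(rng.uniform(250.0, 450.0)),
                branch_diameter=float(rng.uniform(30.0, 60.0)),
                bud_length=float(rng.uniform(150.0, 300.0)),
                bud_diameter=float(rng.uniform(40.0, 60.0)),
                bud_angle_deg=float(rng.uniform(50.0, 90.0)),
                leaves=tuple(leaves),
            )
        )
    return specs
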