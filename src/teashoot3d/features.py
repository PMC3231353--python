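"""Morphological feature extraction from binary shoot masks.

Given the binary mask of a segmented shoot organ (leaf, branch or bud) the
module recovers the measurements used to parameterize the 3D model, all in
pixel units:

* the closed outer **contour** (Moore-neighbor boundary following),
* the **central axis** (morphological skeleton, spur-pruned, ordered, and
  extended to the organ outline so its arc length spans the full organ),
* polyline **subdivision** (deviation-bounded vertex reduction followed by
  corner-cutting smoothing) to turn pixel staircases into smooth curves,
* **leaf length/width**, **branch length/diameter** and the **inclination
  angle** between a leaf vein and the branch axis at the attachment point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

__all__ = [
    "Contour",
    "Axis",
    "LeafFeatures",
    "ShootFeatures",
    "binarize",
    "trace_boundary",
    "central_axis",
    "subdivide_curve",
    "reduce_polyline",
    "chaikin_smooth",
    "measure_leaf",
    "measure_branch",
    "inclination_angle",
    "extract_shoot_features",
]


@dataclass(frozen=True)
class Contour:
    """Closed boundary pixel sequence of one connected component.

    ``points`` is an ``(n, 2)`` array of (row, col) coordinates; consecutive
    points are 8-adjacent and the last point is 8-adjacent to the first.
    """

    points: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Axis:
    """Ordered open polyline of an organ's central axis, (row, col) coords."""

    points: np.ndarray

    @property
    def length(self) -> float:
        """Arc length in pixels."""
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def reversed(self) -> "Axis":
        return Axis(points=self.points[::-1].copy())


@dataclass
class LeafFeatures:
    order: int
    length: float
    width: float
    inclination_deg: float


@dataclass
class ShootFeatures:
    """Measured parameter set of one shoot, pixel units.

    Angles follow the convention: inclination is measured between the
    apex-ward branch tangent and the organ's base tangent, reported in
    [0, 180] degrees (angles beyond 90 mean the organ droops past
    perpendicular).
    """

    leaves: list = field(default_factory=list)  # LeafFeatures, ordered by leaf order
    branch_length: float = 0.0
    branch_diameter: float = 0.0
    bud_length: float = 0.0
    bud_diameter: float = 0.0
    bud_angle_deg: float = 0.0

    def to_json(self, path=None) -> str:
        payload = {
            "angle_convention": "degrees in [0,180] between apex-ward branch tangent and organ base tangent",
            "units": "pixels",
            "leaves": [
                {
                    "order": lf.order,
                    "length": lf.length,
                    "width": lf.width,
                    "inclination_deg": lf.inclination_deg,
                }
                for lf in self.leaves
            ],
            "branch_length": self.branch_length,
            "branch_diameter": self.branch_diameter,
            "bud_length": self.bud_length,
            "bud_diameter": self.bud_diameter,
            "bud_angle_deg": self.bud_angle_deg,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "ShootFeatures":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        leaves = [
            LeafFeatures(
                order=d["order"], length=d["length"], width=d["width"],
                inclination_deg=d["inclination_deg"],
            )
            for d in payload.get("leaves", [])
        ]
        return cls(
            leaves=leaves,
            branch_length=payload.get("branch_length", 0.0),
            branch_diameter=payload.get("branch_diameter", 0.0),
            bud_length=payload.get("bud_length", 0.0),
            bud_diameter=payload.get("bud_diameter", 0.0),
            bud_angle_deg=payload.get("bud_angle_deg", 0.0),
        )


# ---------------------------------------------------------------------------
# binarization and boundary following


def binarize(image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a mask or grayscale image; foreground is the shoot."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        out = arr.copy()
    else:
        out = arr > threshold
    if not out.any():
        warnings.warn("binarization produced an empty foreground", stacklevel=2)
    return out


# clockwise Moore neighborhood starting west, as (dr, dc)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_component(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbor boundary trace of one component.

    The walk starts at the topmost-leftmost pixel scanning from the west
    and stops, per Jacob's criterion, when the (pixel, scan-direction)
    state recurs — i.e. the start is re-entered the same way it first was.
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # topmost-leftmost
    h, w = mask.shape

    def fg(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return np.array([start])

    cur, scan = start, 0
    states: dict[tuple, int] = {}
    seq: list[tuple[int, int]] = []
    while (cur, scan) not in states:
        states[(cur, scan)] = len(seq)
        seq.append(cur)
        for k in range(8):
            d = (scan + k) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(nr, nc):
                break
        cur = (nr, nc)
        # resume scanning just past the pixel we came from
        scan = (d + 5) % 8
    return np.array(seq[states[(cur, scan)] :])


def trace_boundary(binary: np.ndarray) -> list[Contour]:
    """Trace the closed outer boundary of every 8-connected component.

    Contours are returned in counter-clockwise order in (x=col, y=-row)
    coordinates, one per component, largest component first.
    """
    mask = np.asarray(binary, dtype=bool)
    if not mask.any():
        return []
    labels = cc_label(mask, connectivity=2)
    contours = []
    comp_ids, counts = np.unique(labels[labels > 0], return_counts=True)
    for cid in comp_ids[np.argsort(-counts)]:
        pts = _trace_component(labels == cid)
        if len(pts) >= 3:
            # signed area in (x, y) = (col, -row); positive = CCW
            x, y = pts[:, 1].astype(float), -pts[:, 0].astype(float)
            area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
            if area2 < 0:
                pts = pts[::-1]
        contours.append(Contour(points=pts))
    return contours


# ---------------------------------------------------------------------------
# curve subdivision: vertex reduction + corner-cutting smoothing


def _point_segment_dist(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def reduce_polyline(points: np.ndarray, tol: float) -> np.ndarray:
    """Deviation-bounded vertex reduction (Douglas-Peucker).

    The output is a subset of the input vertices, includes both endpoints,
    and deviates from the input polyline by at most ``tol`` pixels.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) <= 2:
        return pts.copy()
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        d = _point_segment_dist(pts[i + 1 : j], pts[i], pts[j])
        k = int(np.argmax(d))
        if d[k] > tol:
            mid = i + 1 + k
            keep[mid] = True
            stack.append((i, mid))
            stack.append((mid, j))
    return pts[keep]


def chaikin_smooth(points: np.ndarray, n_iters: int = 1) -> np.ndarray:
    """Chaikin corner-cutting; endpoints are preserved on open polylines."""
    pts = np.asarray(points, dtype=np.float64)
    for _ in range(n_iters):
        if len(pts) < 3:
            break
        q = 0.75 * pts[:-1] + 0.25 * pts[1:]  # 1/4 point of each segment
        r = 0.25 * pts[:-1] + 0.75 * pts[1:]  # 3/4 point of each segment
        mid = np.empty((2 * (len(pts) - 1) - 2, pts.shape[1]))
        mid[0::2] = r[:-1]
        mid[1::2] = q[1:]
        pts = np.vstack([pts[:1], mid, pts[-1:]])
    return pts


def subdivide_curve(points: np.ndarray, tol: float, smooth_iters: int = 0) -> np.ndarray:
    """Two-phase curve subdivision: reduce vertices, then cut corners.

    Phase one removes vertices while keeping the polyline within ``tol``
    pixels of the original (so pixel staircases collapse to their underlying
    straight runs); phase two applies ``smooth_iters`` rounds of Chaikin
    corner cutting, which converges toward a smooth quadratic B-spline
    through repeated 1/4-3/4 subdivision while preserving the endpoints.
    """
    if len(np.asarray(points)) < 2:
        raise ValueError("need at least 2 points")
    out = reduce_polyline(points, tol)
    if smooth_iters > 0:
        out = chaikin_smooth(out, smooth_iters)
    return out


# ---------------------------------------------------------------------------
# central axis


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rr, cc = np.nonzero(skel)
    nodes = set(zip(rr.tolist(), cc.tolist()))
    for (r, c) in nodes:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in nodes:
                    g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _prune_spurs(g: nx.Graph, edt: np.ndarray, prune_len: float, spur_factor: float) -> nx.Graph:
    """Iteratively remove endpoint branches that are skeletonization
    artifacts: shorter than ``max(prune_len, spur_factor * edt[junction])``."""
    g = g.copy()
    while True:
        if g.number_of_nodes() <= 2:
            break
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        to_remove = set()
        for e in endpoints:
            path = [e]
            cur, prev = e, None
            length = 0.0
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if g.degree(cur) >= 3 and cur != e:
                    break  # reached a junction
                if not nbrs:
                    path = None  # simple path end-to-end: not a spur
                    break
                prev, cur = cur, nbrs[0]
                length += float(np.hypot(cur[0] - prev[0], cur[1] - prev[1]))
                path.append(cur)
            if path is None:
                continue
            junction = path[-1]
            limit = max(prune_len, spur_factor * float(edt[junction]))
            if length < limit:
                to_remove.update(path[:-1])
        if not to_remove:
            break
        g.remove_nodes_from(to_remove)
        if g.number_of_nodes() == 0:
            break
    return g


def _extend_to_boundary(points: np.ndarray, mask: np.ndarray, back: float = 6.0) -> np.ndarray:
    """Extend both polyline ends along their local tangent until the mask
    boundary, so the axis spans the full organ (the skeleton of a rounded
    or pointed shape stops short of the outline)."""
    pts = points.astype(np.float64)
    h, w = mask.shape

    def extend(end_pt, ref_pt):
        d = end_pt - ref_pt
        nrm = np.linalg.norm(d)
        if nrm < 1e-9:
            return None
        d = d / nrm
        p = end_pt.copy()
        last_inside = None
        for _ in range(int(4 * max(mask.shape))):
            p = p + 0.5 * d
            ri, ci = int(round(p[0])), int(round(p[1]))
            if not (0 <= ri < h and 0 <= ci < w) or not mask[ri, ci]:
                break
            last_inside = p.copy()
        return last_inside

    def ref_index(from_start: bool):
        # walk back along the polyline by `back` pixels of arc
        idx = 0 if from_start else len(pts) - 1
        step = 1 if from_start else -1
        acc = 0.0
        j = idx
        while 0 <= j + step < len(pts) and acc < back:
            acc += float(np.linalg.norm(pts[j + step] - pts[j]))
            j += step
        return j

    out = [pts]
    j = ref_index(from_start=False)
    tail = extend(pts[-1], pts[j]) if j != len(pts) - 1 else None
    if tail is not None:
        out.append(tail[None, :])
    pts2 = np.vstack(out)
    j = ref_index(from_start=True)
    head = extend(pts2[0], pts[j]) if j != 0 else None
    if head is not None:
        pts2 = np.vstack([head[None, :], pts2])
    return pts2


def _recenter_axis(points: np.ndarray, mask: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Snap each axis point to the midpoint of the perpendicular mask chord.

    Morphological thinning can drift a pixel or two off the true centerline
    on narrow diagonal shapes; recentring on the chord midpoints removes
    that bias.  Endpoints are kept fixed.
    """
    m = np.asarray(mask, dtype=np.uint8)
    pts = _resample_polyline(points, spacing=2.0)
    if len(pts) < 5:
        return np.asarray(points, dtype=np.float64)
    rmax = float(ndimage.distance_transform_edt(m).max())
    half = min(2.5 * rmax + 2.0, float(min(m.shape)))
    offs = np.arange(-half, half + 0.25, 0.25)
    c0 = int(np.argmin(np.abs(offs)))
    for _ in range(n_iter):
        tan = _tangents(pts)
        nrm = np.column_stack([-tan[:, 1], tan[:, 0]])
        rows = pts[:, 0][:, None] + nrm[:, 0][:, None] * offs[None, :]
        cols = pts[:, 1][:, None] + nrm[:, 1][:, None] * offs[None, :]
        inside = ndimage.map_coordinates(
            m, [rows.ravel(), cols.ravel()], order=0, cval=0
        ).reshape(rows.shape).astype(bool)
        left = inside[:, : c0 + 1][:, ::-1]
        right = inside[:, c0:]
        lf = np.argmin(left, axis=1)
        lf[left.all(axis=1)] = left.shape[1]
        rf = np.argmin(right, axis=1)
        rf[right.all(axis=1)] = right.shape[1]
        ok = inside[:, c0].copy()
        mid = (offs[np.maximum(c0 - lf + 1, 0)] + offs[np.minimum(c0 + rf - 1, len(offs) - 1)]) / 2.0
        # the thinning bias being corrected is small; clip and smooth the
        # shifts so oblique chords near ends cannot derail the path
        shift = np.clip(np.where(ok, mid, 0.0), -3.0, 3.0)
        # endpoints often sit on the outline where the chord degenerates;
        # inherit the neighboring shift rather than freezing the old bias
        if not ok[0]:
            shift[0] = shift[1]
        if not ok[-1]:
            shift[-1] = shift[-2]
        shift = ndimage.uniform_filter1d(shift, size=7, mode="nearest")
        pts = pts + nrm * shift[:, None]
    return pts


def central_axis(
    binary: np.ndarray,
    prune_len: float = 10.0,
    spur_factor: float = 1.7,
    smooth_tol: float = 2.0,
    extend: bool = True,
    recenter: bool = True,
) -> Axis:
    """Central axis of a single connected component.

    The mask is thinned to a 1-pixel skeleton; endpoint spurs shorter than
    ``max(prune_len, spur_factor * local_radius)`` are removed (these are
    corner artifacts of thinning — e.g. the diagonal branches at the ends
    of a thick rectangle); the main axis is the longest geodesic path
    through the remaining skeleton.  The path is then extended along its
    end tangents to the component outline, simplified with tolerance
    ``smooth_tol`` and corner-smoothed, and returned ordered from the
    endpoint with the smaller (row, col).
    """
    mask = np.asarray(binary, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no central axis")
    n_comp = cc_label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"central_axis expects a single component, found {n_comp}")
    if mask.sum() == 1:
        r, c = np.argwhere(mask)[0]
        return Axis(points=np.array([[float(r), float(c)]]))

    skel = skeletonize(mask)
    if not skel.any():  # degenerate: thinning ate everything
        skel = mask.copy()
    edt = ndimage.distance_transform_edt(mask)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() == 0:
        raise ValueError("skeletonization produced no axis")
    # keep the largest connected piece of the skeleton
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    g = _prune_spurs(g, edt, prune_len, spur_factor)
    if g.number_of_nodes() == 0:
        g = _skeleton_graph(skel)
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()

    # tree-diameter heuristic: farthest node from an arbitrary node, then
    # farthest from that — exact on trees, good on near-trees
    n0 = next(iter(g.nodes))
    dist = nx.single_source_dijkstra_path_length(g, n0)
    a = max(dist, key=dist.get)
    dist_a, paths_a = nx.single_source_dijkstra(g, a)
    b = max(dist_a, key=dist_a.get)
    path = np.array(paths_a[b], dtype=np.float64)
    if len(path) < 3:
        # skeleton collapsed to (nearly) a point — e.g. a disk; take the
        # shape's principal axis through that point as the direction
        center = path.mean(axis=0)
        pix = np.argwhere(mask).astype(np.float64)
        _, _, vt = np.linalg.svd(pix - pix.mean(axis=0), full_matrices=False)
        d = vt[0]
        path = np.vstack([center - d, center, center + d])

    if recenter and len(path) > 2:
        path = _recenter_axis(path, mask)
    if smooth_tol > 0 and len(path) > 2:
        path = subdivide_curve(path, tol=smooth_tol, smooth_iters=2)
    if recenter and len(path) > 2:
        # corner-cutting pulls the path inward on bends; recenter once
        # more, then smooth gently (tight tolerance, one corner cut) so
        # chord-midpoint jitter does not inflate the arc length
        path = _recenter_axis(path, mask, n_iter=1)
        if smooth_tol > 0 and len(path) > 2:
            path = subdivide_curve(path, tol=min(smooth_tol, 1.0), smooth_iters=1)
    if extend:
        path = _extend_to_boundary(path, mask)
    first, last = tuple(path[0]), tuple(path[-1])
    if last < first:
        path = path[::-1]
    return Axis(points=path)


# ---------------------------------------------------------------------------
# measurements


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        return pts.copy()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        return pts[:1].copy()
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, pts.shape[1]))
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(t, arc, pts[:, d])
    return out


def _tangents(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    t = np.gradient(pts, axis=0)
    nrm = np.linalg.norm(t, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return t / nrm


def _max_perpendicular_chord(mask: np.ndarray, axis_pts: np.ndarray, step: float = 0.5) -> float:
    """Maximum mask chord perpendicular to the local axis direction."""
    pts = _resample_polyline(axis_pts, spacing=2.0)
    if len(pts) < 2:
        return 0.0
    tan = _tangents(pts)
    nrm = np.column_stack([-tan[:, 1], tan[:, 0]])  # perpendicular in (row, col)
    max_half = float(min(mask.shape)) * 0.75
    offs = np.arange(-max_half, max_half + step, step)
    c0 = int(np.argmin(np.abs(offs)))
    rows = pts[:, 0][:, None] + nrm[:, 0][:, None] * offs[None, :]
    cols = pts[:, 1][:, None] + nrm[:, 1][:, None] * offs[None, :]
    inside = ndimage.map_coordinates(
        mask.astype(np.uint8), [rows.ravel(), cols.ravel()], order=0, cval=0
    ).reshape(rows.shape).astype(bool)
    # contiguous run of foreground containing the axis point
    best = 0.0
    left = inside[:, : c0 + 1][:, ::-1]  # from center outward
    right = inside[:, c0:]
    # first gap position on each side
    lf = np.argmin(left, axis=1)
    lf[left.all(axis=1)] = left.shape[1]
    rf = np.argmin(right, axis=1)
    rf[right.all(axis=1)] = right.shape[1]
    on_axis = inside[:, c0]
    chords = (lf + rf - 1).astype(float) * step
    chords[~on_axis] = 0.0
    if len(chords):
        best = float(chords.max())
    return best


def measure_leaf(mask: np.ndarray, vein: Axis) -> tuple[float, float]:
    """Leaf length (vein arc length) and maximum width perpendicular to it."""
    if len(vein.points) < 2 or vein.length <= 0:
        raise ValueError("degenerate vein axis")
    ll = vein.length
    lw = _max_perpendicular_chord(np.asarray(mask, dtype=bool), vein.points)
    return ll, lw


def measure_branch(mask: np.ndarray, axis: Axis) -> tuple[float, float]:
    """Branch length (axis arc length) and mean diameter.

    The diameter is twice the distance-transform value sampled along the
    axis, averaged over the portion of the axis more than one maximum
    radius away from either end (the end caps bias the distance transform
    downward).
    """
    if len(axis.points) < 2 or axis.length <= 0:
        raise ValueError("degenerate branch axis")
    m = np.asarray(mask, dtype=bool)
    edt = ndimage.distance_transform_edt(m)
    pts = _resample_polyline(axis.points, spacing=1.0)
    radii = ndimage.map_coordinates(edt, [pts[:, 0], pts[:, 1]], order=1)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    rmax = float(radii.max()) if len(radii) else 0.0
    total = arc[-1]
    keep = (arc >= rmax) & (arc <= total - rmax)
    if keep.sum() < 2:
        keep = np.ones_like(keep, dtype=bool)
    # the EDT measures to background pixel centers, half a pixel beyond
    # the true outline on each side
    diameter = max(2.0 * float(np.mean(radii[keep])) - 1.0, 1.0)
    return axis.length, diameter


def _direction(points: np.ndarray, arc_span: float) -> np.ndarray:
    """Unit chord direction over the first ``arc_span`` pixels of a polyline."""
    pts = np.asarray(points, dtype=np.float64)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    j = int(np.searchsorted(arc, arc_span))
    j = min(max(j, 1), len(pts) - 1)
    d = pts[j] - pts[0]
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("cannot estimate direction of a degenerate polyline")
    return d / n


def inclination_angle(
    leaf_vein: Axis, branch_axis: Axis, max_attach_dist: float = 60.0
) -> float:
    """Angle in degrees between a leaf vein and the branch at attachment.

    ``branch_axis`` must be ordered base-to-apex.  The attachment is the
    leaf-vein endpoint nearest the branch axis (the vein is reoriented to
    start there); the angle is between the vein's base tangent and the
    apex-ward branch tangent at the attachment, in [0, 180].
    """
    if len(leaf_vein.points) < 2 or len(branch_axis.points) < 2:
        raise ValueError("both axes need at least 2 points")
    bpts = _resample_polyline(branch_axis.points, spacing=1.0)
    d_first = np.min(np.linalg.norm(bpts - leaf_vein.points[0], axis=1))
    d_last = np.min(np.linalg.norm(bpts - leaf_vein.points[-1], axis=1))
    vein = leaf_vein if d_first <= d_last else leaf_vein.reversed()
    attach_dist = min(d_first, d_last)
    if attach_dist > max_attach_dist:
        raise ValueError(
            f"leaf vein is {attach_dist:.1f} px from the branch axis "
            f"(> {max_attach_dist}); not attached"
        )
    attach_idx = int(np.argmin(np.linalg.norm(bpts - vein.points[0], axis=1)))

    span_v = max(10.0, 0.10 * vein.length)
    u = _direction(vein.points, span_v)

    span_b = max(10.0, 0.10 * float(np.sum(np.linalg.norm(np.diff(bpts, axis=0), axis=1))))
    j = min(attach_idx + int(span_b), len(bpts) - 1)
    i = max(attach_idx - int(span_b), 0)
    if j == attach_idx:
        j = attach_idx
        i = max(0, attach_idx - int(span_b))
    v = bpts[j] - bpts[i]
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("degenerate branch tangent at attachment")
    v = v / nv
    cosang = float(np.clip(u @ v, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# full extraction pipeline


def extract_shoot_features(organ_masks: dict) -> ShootFeatures:
    """Measure a full shoot from per-organ binary masks.

    ``organ_masks`` maps organ names to boolean masks: ``'branch'``,
    optionally ``'bud'``, and leaves as ``'leaf_<order>'``.  The branch
    axis is oriented base-to-apex using the bud position (or the first
    leaf's attachment if no bud is present).
    """
    if "branch" not in organ_masks:
        raise ValueError("organ_masks must contain a 'branch' mask")
    branch_mask = np.asarray(organ_masks["branch"], dtype=bool)
    branch_axis = central_axis(branch_mask)
    b_len, b_dia = measure_branch(branch_mask, branch_axis)

    # orient branch base->apex: apex is the end nearest the bud (or leaf 1)
    ref = None
    if "bud" in organ_masks:
        ref = np.argwhere(organ_masks["bud"]).mean(axis=0)
    else:
        leaf_keys = sorted(k for k in organ_masks if k.startswith("leaf_"))
        if leaf_keys:
            ref = np.argwhere(organ_masks[leaf_keys[0]]).mean(axis=0)
    if ref is not None:
        d_start = np.linalg.norm(branch_axis.points[0] - ref)
        d_end = np.linalg.norm(branch_axis.points[-1] - ref)
        if d_start < d_end:
            branch_axis = branch_axis.reversed()

    feats = ShootFeatures(branch_length=b_len, branch_diameter=b_dia)

    for key in sorted(k for k in organ_masks if k.startswith("leaf_")):
        order = int(key.split("_", 1)[1])
        mask = np.asarray(organ_masks[key], dtype=bool)
        vein = central_axis(mask)
        ll, lw = measure_leaf(mask, vein)
        ang = inclination_angle(vein, branch_axis)
        feats.leaves.append(
            LeafFeatures(order=order, length=ll, width=lw, inclination_deg=ang)
        )
    feats.leaves.sort(key=lambda lf: lf.order)

    if "bud" in organ_masks:
        mask = np.asarray(organ_masks["bud"], dtype=bool)
        vein = central_axis(mask)
        ll, lw = measure_leaf(mask, vein)
        feats.bud_length = ll
        feats.bud_diameter = lw
        feats.bud_angle_deg = inclination_angle(vein, branch_axis)
    return feats
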