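# Methods

`teashoot3d` models a tea shoot — the terminal bud plus the first tender
leaves on a short branch — from a single color photograph: segment the
shoot, measure its morphology in pixels, and rebuild it as a parametric 3D
scene.  This note records the models, the parameter choices and the
numerical decisions behind each stage, and what the synthetic test data do
and do not establish.

## Color space

Segmentation runs on hue and saturation because the tender-shoot /
mature-leaf contrast is chiefly a hue shift that survives brightness
changes.  RGB in [0, 1] converts to geometric (arccos-form) HSI:
`I = (R+G+B)/3`, `S = 1 − min/I`, `H` from the arccos of the chroma
projection, in degrees.  Conventions that had to be fixed for reproducible
distances: achromatic pixels (including black) get `H = 0, S = 0`; hue is
treated as circular everywhere (minimal angular difference, circular
means), so there is no discontinuity at 0°/360°.

## Segmentation

1. **Seeds.** Pixels are quantized in (H, S) — `n_levels` hue bins over
   360° (default 36, i.e. 10° bins) × `s_levels` saturation bins (default
   4).  Every 4-connected component of one quantized code with at least
   `min_area` pixels becomes a seed region.  `min_area` is a true free
   parameter of the method: 100 px is the library default for photograph-
   scale input; the segmentation-exactness runs use 10 px so that small
   enclosed background pockets between crossing organs can seed their own
   regions rather than being absorbed into the shoot.  If nothing reaches
   `min_area` the caller is warned and may seed manually.
2. **Growing and merging.** Unseeded pixels start as singleton regions.
   The engine repeatedly merges the adjacent pair with the globally
   smallest size-weighted color distance
   `Dc = r_i r_j/(r_i + r_j) · ‖μ_i − μ_j‖`, requiring strictly
   `Dc < 12` (hue-degree scale) **and** edge distance
   `De = (1/P)·Σ‖x_m − x_n‖ < de_threshold` across the shared boundary.
   `De` keeps regions apart when their means are close but the boundary is
   a hard color step; smooth ramps merge.  The `De` threshold is not fixed
   by the method's published description; the default of 10 (same
   hue-degree scale as `Dc`) was chosen on synthetic fixtures so that
   jitter-level transitions merge while class boundaries (≥ 20° hue steps)
   block.  The color vector is (H in degrees, S in [0, 1]) with circular
   H; an H-only mode exists (`mode="h"`).  Since S spans only [0, 1]
   against hue's degrees, the hue component dominates by construction.
3. **Determinism.** Ties on the smallest `Dc` break on the lexicographically
   smallest region-id pair; the merged region keeps the smaller id; region
   means are maintained as exact vector sums (cos/sin for hue), so the
   incremental engine reproduces a from-scratch exhaustive recompute — the
   test suite verifies partition-level equality against such an oracle on
   100 random small images.
4. **Termination.** Regions still lacking a seed when no admissible pair
   remains are absorbed into the adjacent region with the closest mean
   color (smallest id first), so the label map always partitions the
   raster.  Shoot classification then flags every region whose circular-
   mean hue falls in the shoot hue window (default 55-95°, the lighter
   yellow-green band); disjoint shoot blobs are all flagged.

## Feature extraction

All measurements are in pixel units; no metric calibration is attempted.

* **Contours** — Moore-neighbor tracing with Jacob's stopping criterion
  (stop when the start pixel is re-entered the same way), oriented
  counter-clockwise.
* **Central axis** — morphological thinning, then spur pruning: an
  endpoint branch is removed when shorter than
  `max(prune_len, spur_factor · EDT(junction))` with `prune_len = 10` px
  and `spur_factor = 1.7`; this removes the diagonal corner artifacts at
  the ends of thick rectangles, whose length scales with the local radius.
  The main axis is the longest geodesic path through the remaining
  skeleton.  Thinning drifts up to ~2 px off-center on narrow diagonal
  shapes, so the path is re-centered on perpendicular-chord midpoints
  (shifts clipped to ±3 px and smoothed along the path), simplified
  (Douglas-Peucker, 2 px) and corner-smoothed (two Chaikin rounds),
  re-centered once more (corner cutting pulls inward on bends), and
  finally extended along its end tangents to the outline — the skeleton of
  a rounded or pointed shape stops about one local radius short of the
  boundary, which would otherwise bias lengths low (e.g. an ellipse's
  medial axis ends at the vertex curvature centers).  If thinning
  collapses to a point (a disk), the shape's principal axis through that
  point is used as the direction.
* **Measurements** — leaf length is the axis arc length; leaf width the
  maximum mask chord perpendicular to the local axis; branch diameter
  twice the mean distance-transform value along the axis, trimmed one
  maximum radius from both ends (end caps bias the EDT down) and corrected
  by −1 px because the EDT measures to background pixel centers, half a
  pixel beyond the outline on each side.  The inclination angle is the
  angle between the vein's base tangent and the apex-ward branch tangent
  at the attachment (the nearer vein endpoint), reported in [0°, 180°]:
  values beyond 90° mean the leaf droops past perpendicular — the
  convention is stated in the JSON output because reflex insertions do
  occur (the reference shoot's second leaf sits at 131.1°).

## Morphology models

* **Vein curve.** The main vein is a cantilever beam clamped at the stem,
  bent by a uniform gravity load.  Only the ratio `kappa = q/(E·I)`
  (1/length³) affects the shape, so the undetermined load and stiffness
  coefficients are collapsed into this one bending parameter.  Integrating
  `E·I·y₁″ = q·sinθ·(L−x₁)²/2` with `y₁(0) = y₁′(0) = 0` gives
  `y₁ = kappa·sinθ/24·(x₁⁴ − 4Lx₁³ + 6L²x₁²)` in the beam frame, rotated
  by the stem-leaf angle θ into the leaf frame.  The clamped boundary
  condition (zero slope in the rotated frame, i.e. the vein leaves the
  stem exactly at angle θ) is the only reading consistent with the quartic
  itself.  The curve is validated against direct numerical integration of
  the beam ODE to 1e−6 relative error.  Gravity points toward −y in the
  leaf frame: the tip sags downward.
* **Leaf length by order.** `LL(N) = LM·exp(La·(N/NM − 1)²)` with `La < 0`
  so the length peaks at order `NM` (a variety parameter); `La > 0` only
  warns, since fitting may explore it.
* **Width profile and area.** `lw/LW = a·s² + b·s + c` on `s = ll/LL`,
  clamped at zero, normalized so the maximum over [0, 1] is 1 (then `LW`
  is the attained maximum).  Whether the width vanishes at the base and
  tip is left to the coefficients — the default `(−4, 4, 0)` does vanish
  at both ends.  The leaf area is `LA = k·LW·LL`; consistency requires
  `k = a/3 + b/2 + c`, the profile integral.  The default profile gives
  `k = 2/3 ≈ 0.667`, at the bottom of the empirical 0.67-0.8 range for
  tea leaves.  Profile fitting is linear least squares on the normalized
  coordinates.

## 3D reconstruction

Image measurements are planar; the third dimension is a parametric lift:
the cantilever curve bends the vein out of its insertion direction
(default tip sag 4% of the vein length, i.e. `kappa` solved from
`sag = kappa·sinθ·L⁴/8`), and the lamina folds upward about the vein by a
small angle (default 20°; 100° for the horn-shaped bud).

* **Branches** are generalized cylinders: an `n_sides` polygon (default
  16) swept along the skeleton with parallel-transport frames and radius
  linearly interpolated in arc length, closed by end caps — watertight by
  construction.
* **Leaves** sample the vein at `n_edge_vertices` stations (9 by default,
  valid range 8-10; an override flag exists for convergence studies) and
  place outline vertices at ± half the local width perpendicular to the
  vein, rotated by ± half the fold angle.  Two triangles per station
  interval per side (`4(m−1)` total) fan between vein and outline; the
  outline endpoints coincide with the vein head and tail, so the mesh is a
  disk with a single boundary loop.  Texture coordinates map the vein to
  `v = 0.5` with the outline spreading toward 0 and 1.  Each leaf carries
  a two-slot texture reference: a generic template texture first,
  overwritten by a segmented-image crop when available; template matching
  picks the database leaf minimizing the scale-optimal (LL, LW) residual,
  ties broken by template id.
* **Assembly** places the branch vertically, attaches leaf `N` at height
  fraction `0.8 − 0.3(N−1)` (clamped at 0.2) with azimuths alternating by
  180° (opposite insertion), and the bud at the apex.  Measuring the
  assembled geometry returns the input inclination angles to under 0.5°.
* **Growth** is staged — bud, expansion, formation — with per-stage linear
  multiplier schedules on LL, LW, θ and kappa.  The defaults start at 1
  (the input model is the bud-stage origin, so `t = 0` is the identity),
  keep LL and LW non-decreasing, open the angle through expansion, and
  freeze elongation in formation (≤ 1% change, validated).  Branch
  dimensions are held constant: the shoot's branch is essentially formed
  when picking matters, and no quantitative branch-growth law is
  available.  Absolute θ schedules are supported for calibrated stages.
  Exports are ASCII OBJ (+MTL when textured) or ASCII PLY, 1e−6
  coordinate precision.

## Synthetic data

The generator renders the same parametric morphology the reconstruction
uses: cantilever veins (default tip sag 4% of length), quadratic width
profiles, a rectangular branch, all rasterized hard-edged (no
anti-aliasing) so the ground-truth label map is exact; per-pixel hue and
saturation jitter and Gaussian blur are available for robustness tests,
and a two-class mode paints the branch in the shoot color for pure
foreground/background experiments.  The default spec reproduces the
reference shoot's measured parameters (leaves 417×118 px at 49.8° and
779×325 px at 131.1°, branch 321×51 px, bud 298×55 px at 75.8°); the
randomized suite draws leaf length 200-800 px, width 80-350 px (capped at
0.55× length), inclination 30-140°, branch 250-450 × 30-60 px, bud
150-300 × 40-60 px at 50-90°, mirroring those magnitudes.  All randomness
flows from one seed.

What passing tests on these fixtures show: the algorithms are internally
consistent — measurement inverts rendering to ~1% on lengths/widths and
~1-2° on angles, and segmentation is exact when the class hues are exact.
What they do not show: performance on real field photographs, which add
lighting gradients, shadows, serrated and damaged leaf margins, occlusion
and camera noise that the generator deliberately omits.

## Problem sizes in the validation runs

The test suite and the acceptance script use 100 random draws for the
cantilever oracle, 100 random ≤16×16 images for the merge-oracle
equality, 20 noiseless two-class fixtures for segmentation exactness, and
a 50-fixture randomized population (plus the reference-parameter fixture)
for recovery statistics — large enough for stable medians while keeping a
full run in a few minutes on one core.

## Known limitations

* The `De` threshold and seed `min_area` are data-scale dependent; the
  defaults suit photograph-scale hue contrasts and need adjustment for
  other imagery.
* Enclosed background pockets smaller than `min_area` cannot seed and are
  absorbed into a surrounding region — the one structural failure mode of
  the label-map-partition guarantee.
* Boundary tracing revisits pixels on 1-px-wide prongs (inherent to
  Moore tracing on thin structures).
* The growth schedules are qualitative shape laws, not calibrated to
  seasonal growth-rate data; side veins and margin serration are not
  modeled.
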