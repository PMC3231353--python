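"""Evaluate the tea-leaf morphology models.

The vein is a gravity-loaded cantilever beam: deflection
y1 = kappa*sin(theta)/24 * (x^4 - 4Lx^3 + 6L^2x^2).  Leaf length follows a
Gaussian-in-order law peaking at the order of the longest leaf; leaf width
follows a normalized quadratic profile whose integral is the area factor k.
"""

import numpy as np

from teashoot3d.morphology_models import (
    LeafAreaModel,
    LeafLengthModel,
    LeafWidthModel,
    VeinCurveParams,
    leaf_area,
    leaf_length_by_order,
    vein_curve,
)

# vein curves for three bending levels at the first tender leaf's geometry
for kappa in (0.0, 1e-9, 5e-9):
    params = VeinCurveParams(L=417.0, theta=49.8, kappa=kappa)
    pts = vein_curve(params, n_samples=200)
    sag = params.kappa * np.sin(np.radians(params.theta)) * params.L**4 / 8.0
    arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    print(f"kappa={kappa:.1e}: tip sag {sag:7.2f} px, arc length {arc:7.2f} px")
# kappa = q/(E*I) bundles load and stiffness; zero gives the straight leaf.

# leaf length along the branch for a variety peaking at order 2
model = LeafLengthModel(LM=779.0, NM=2.0, La=-0.8)
for order in range(1, 6):
    print(f"leaf order {order}: predicted length {leaf_length_by_order(model, order):6.1f} px")

# width profile and area of the first tender leaf
wm = LeafWidthModel(a=-4.0, b=4.0, c=0.0, LW=118.0, LL=417.0)
area = leaf_area(LeafAreaModel(k=0.7), 118.0, 417.0)
print(f"width-profile area factor k = {wm.k:.4f}")
print(f"leaf area with mid-range k=0.7: {area:.0f} px^2")
# k = 2/3 for the default parabolic profile, at the low end of the
# empirical 0.67-0.8 range for tea leaves.
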