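"""Simulate the three-stage formation of a tea leaf.

A tea leaf forms in three stages: the bud period (curved, horn-shaped),
leaf expansion (the stem-leaf angle opens and the lamina spreads) and leaf
formation (elongation essentially stops).  The simulation re-assembles the
3D model with stage-dependent multipliers on length, width, inclination
and bending.
"""

from teashoot3d.features import LeafFeatures, ShootFeatures
from teashoot3d.reconstruction import GrowthStage, assemble_shoot, simulate_growth

feats = ShootFeatures(
    leaves=[LeafFeatures(1, 200.0, 70.0, 40.0)],
    branch_length=300.0,
    branch_diameter=40.0,
)
model = assemble_shoot(feats)

print(f"{'stage':12s} {'t':>4s} {'LL (px)':>8s} {'LW (px)':>8s} {'theta':>7s} {'area':>9s}")
for stage in ("bud", "expansion", "formation"):
    for t in (0.0, 0.5, 1.0):
        grown = simulate_growth(model, GrowthStage(stage, t))
        lf = grown.features.leaves[0]
        area = (2.0 / 3.0) * lf.width * lf.length
        print(f"{stage:12s} {t:4.1f} {lf.length:8.1f} {lf.width:8.1f} "
              f"{lf.inclination_deg:6.1f} {area:9.0f}")
# length and width never decrease, the inclination angle opens through
# expansion, and elongation halts (<= 1% change) in the formation stage.
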