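"""Rank compounds against a lead by shape + pharmacophore Tanimoto.

Builds a lead molecule, three rigidly moved near-copies (its "chemical
family") and three unrelated molecules, then ranks everything against the
lead by the combo score tc_shape + tc_color.  The family should occupy the
top of the ranking with combo near 2; unrelated shapes score low, and their
color term collapses when no pharmacophore types line up.
"""

import numpy as np

import dockoverlap as d
from dockoverlap.shape import RigidTransform

rng = np.random.default_rng(0)
lead = d.make_compound(14, seed=51, id="lead")

probes = []
for k in range(3):
    jittered = lead.coords + rng.normal(0, 0.15, lead.coords.shape)
    probes.append(RigidTransform.random(rng).apply_pose(
        lead.with_coords(jittered, id=f"family_{k}")))
probes += [d.make_compound(25, seed=s, id=f"unrelated_{s}") for s in (61, 62, 63)]

print(f"{'id':>12}  {'tc_shape':>8}  {'tc_color':>8}  {'tc_combo':>8}")
for pid, score in d.rank_by_combo(lead, probes):
    print(f"{pid:>12}  {score.tc_shape:8.3f}  {score.tc_color:8.3f}  {score.tc_combo:8.3f}")
print("\ncombo = shape + color in [0, 2]; jittered copies of the lead rank "
      "first, unrelated shapes trail.")

vn = d.normalized_volumes([lead] + probes)
print("\nnormalized vdW volumes (largest compound = 1):")
for pid, v in sorted(vn, key=lambda t: -t[1]):
    print(f"  {pid:>12}  Vn = {v:.3f}")
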