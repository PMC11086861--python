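"""Locate and name every disc and vertebra on a segmented study.

The merged sacrum+disc+vertebra region is thinned to a one-pixel
centerline, ordered bottom-to-top with A* (branches pruned), and the
structures encountered along the walk are named L5/S1, L4/L5, ... and
L5, L4, ...
"""

from spineannot import PhantomConfig, generate
from spineannot.spine_topology import assign_names, extract_skeleton, order_path

study = generate(PhantomConfig(seed=7, n_ivds=4, grades=(2, 2, 3, 4), bump=True))

skeleton = extract_skeleton(study.labels)
path = order_path(skeleton)
named = assign_names(path, study.labels)

print(f"skeleton endpoints: {len(skeleton.endpoints)} (bump adds a branch)")
print(f"path: {len(path.points)} points from {path.start} (sacrum) to {path.finish} (top)")
for s in named.ivds + named.vertebrae:
    print(f"  {s.name:6s} area {s.ccr.area_px:5d} px")
# Names are assigned purely by traversal order, so they match the
# generator's bottom-up construction exactly.
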