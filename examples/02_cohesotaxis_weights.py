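"""Cohesotaxis weight vectors for different bias strengths kappa.

A leader's free-edge voxels are sorted by cumulative distance to its
cell-cell contacts; a new lamellipodium direction is sampled with these
normalized sigmoid weights.  kappa = -6 is near-uniform (no bias);
kappa = +6 puts essentially all mass on the voxels farthest from the
contacts, i.e. the forward direction.
"""

import numpy as np

from mesocpm import bias_weights

n = 12
for kappa in (-6.0, -2.0, 0.0, 2.0, 6.0):
    w = bias_weights(n, kappa)
    bars = " ".join(f"{x:.3f}" for x in w)
    print(f"kappa {kappa:+.0f}: sum={w.sum():.12f}  [{bars}]")
print("\nWeights always sum to 1 and are non-decreasing along the sorted")
print("free-edge list, so larger kappa concentrates protrusion on the")
print("voxels most opposite the cell-cell contacts.")
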