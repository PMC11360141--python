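"""Passive intercalation accelerates ITR closure.

Cell-cell adhesion links break as a Poisson process (rate zeta_tissue per
timestep) and re-form with random neighbors (max 4), letting cells
rearrange.  Upper-layer cells intercalate down to the substrate, the
tissue flattens, and the gap closes faster.
"""

import numpy as np

from mesocpm import SimConfig
from mesocpm.experiments import run_itr_replicate

GEO = dict(margin=5, width_cells=6, length_cells=3, height_cells=2)

for zeta in (0.0, 0.1):
    cfg = SimConfig().replace(zeta_tissue=zeta, itr_gap=30)
    speeds, counts = [], []
    for seed in (0, 1):
        run = run_itr_replicate(cfg, seed, geometry_kw=GEO)
        speeds.append(run.closure_speed_um_h)
        counts.append((int(run.substrate_counts[0]),
                       int(run.substrate_counts[-1])))
    print(f"zeta_tissue={zeta}: closure {np.mean(speeds):.0f} um/h; "
          f"substrate-contacting cells first->last: {counts}")
print("\nWith the rule on (zeta=0.1) more cells reach the substrate over")
print("the run (radial intercalation) and closure is markedly faster.")
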