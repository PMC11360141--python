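"""Shared fixtures: configs, small lattice states, and scaled presets.

The scaled presets (6x3x2-cell explants, 30-voxel ITR gap, tight margins)
keep multi-replicate behavioral tests affordable while preserving the
leader/follower architecture; structural checks use the full-size
defaults.
"""

import numpy as np
import pytest

from mesocpm import SimConfig
from mesocpm.state import SimState, CellType
from mesocpm.links import LinkKind

# scaled-geometry presets shared by behavioral tests
SCALED_DMZ_GEO = dict(width_cells=6, length_cells=3, height_cells=2,
                      forward_margin=45, back_margin=6, side_margin=5)
SCALED_SENS_GEO = dict(width_cells=6, length_cells=3, height_cells=2,
                       forward_margin=50, back_margin=6, side_margin=5)
SCALED_ITR_GEO = dict(width_cells=6, length_cells=3, height_cells=2,
                      margin=5)
SCALED_ITR_GAP = 30


@pytest.fixture
def config():
    return SimConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_two_cell_state(v_edge: int = 3, gap: int = 0,
                        types=(CellType.FOLLOWER, CellType.FOLLOWER)):
    """Two cubic cells side by side on the substrate, medium around."""
    nx = 2 * v_edge + gap + 6
    st = SimState((nx, v_edge + 6, v_edge + 4))
    blocks = []
    for i, t in enumerate(types):
        x0 = 3 + i * (v_edge + gap)
        vox = np.array([(x0 + dx, 3 + dy, 1 + dz)
                        for dx in range(v_edge)
                        for dy in range(v_edge)
                        for dz in range(v_edge)])
        blocks.append(st.add_cell(vox, t))
    return st, blocks


def make_single_cube_state(v_edge: int = 5, ctype=CellType.LEADER,
                           floating: bool = False):
    """One cubic cell; floating=True lifts it off the substrate."""
    pad = 4
    n = v_edge + 2 * pad
    st = SimState((n, n, v_edge + 2 * pad))
    z0 = pad if floating else 1
    vox = np.array([(pad + dx, pad + dy, z0 + dz)
                    for dx in range(v_edge)
                    for dy in range(v_edge)
                    for dz in range(v_edge)])
    cid = st.add_cell(vox, ctype)
    return st, cid


@pytest.fixture
def two_cell_state():
    return make_two_cell_state()


@pytest.fixture
def cube_state():
    return make_single_cube_state()
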