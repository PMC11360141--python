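"""Initial-state builders: substrate, single DMZ explant, and the ITR
four-explant configuration.

A DMZ explant is a block of 8 x 4 x 2 cells (width x length x height),
each cell a 5x5x5-voxel cube (~30 um at 6 um/voxel), resting on a flat
one-voxel substrate plane at z = 0.  The eight bottom-layer cells of the
leading edge are leader agents; everything else is a follower.  The ITR
("in-the-round") configuration places four such explants orthogonally,
facing a central cell-free square, without changing any other parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .links import LinkKind, place_lamellipodium
from .cohesotaxis import free_edge_voxels
from .state import SimState, CellType, SUBSTRATE_ID

_FACING_AXES = {
    "+x": np.array([1.0, 0.0, 0.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "+y": np.array([0.0, 1.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
}


@dataclass
class ExplantSpec:
    """Placement and shape of one rectangular explant."""

    origin: tuple[int, int]  # min (x, y) corner of the footprint
    facing: str = "+x"       # direction of the leading edge
    width_cells: int = 8
    length_cells: int = 4
    height_cells: int = 2
    voxels_per_cell_edge: int = 5

    def __post_init__(self):
        if self.facing not in _FACING_AXES:
            raise ValueError(f"facing must be one of {list(_FACING_AXES)}")

    @property
    def n_cells(self) -> int:
        return self.width_cells * self.length_cells * self.height_cells

    @property
    def footprint(self) -> tuple[int, int]:
        """(x extent, y extent) of the footprint in voxels."""
        e = self.voxels_per_cell_edge
        along, across = self.length_cells * e, self.width_cells * e
        return (along, across) if self.facing in ("+x", "-x") else (across, along)

    def cell_block(self, iw: int, il: int, ih: int) -> np.ndarray:
        """Voxel coordinates of the (iw, il, ih) cell of the grid
        (width, length-from-rear, height-from-substrate indices)."""
        e = self.voxels_per_cell_edge
        x0, y0 = self.origin
        if self.facing == "+x":
            ax, ay = x0 + il * e, y0 + iw * e
        elif self.facing == "-x":
            ax, ay = x0 + (self.length_cells - 1 - il) * e, y0 + iw * e
        elif self.facing == "+y":
            ax, ay = x0 + iw * e, y0 + il * e
        else:  # -y
            ax, ay = x0 + iw * e, y0 + (self.length_cells - 1 - il) * e
        az = 1 + ih * e  # cells sit on top of the z=0 substrate plane
        grid = np.mgrid[ax:ax + e, ay:ay + e, az:az + e]
        return grid.reshape(3, -1).T


@dataclass
class ExplantInfo:
    """Bookkeeping returned by the builders for measurement protocols."""

    facing: str
    axis: np.ndarray                 # signed unit migration axis
    cell_ids: list[int]
    leader_ids: list[int]            # ordered along the width axis
    center_leader_ids: list[int]     # width positions 3-6 of 1-8

    @property
    def follower_ids(self) -> list[int]:
        leaders = set(self.leader_ids)
        return [c for c in self.cell_ids if c not in leaders]


@dataclass
class ITRInfo:
    explants: list[ExplantInfo]
    gap_bounds: tuple[int, int, int, int]  # (x_lo, x_hi, y_lo, y_hi), hi exclusive

    @property
    def gap_area(self) -> int:
        x_lo, x_hi, y_lo, y_hi = self.gap_bounds
        return (x_hi - x_lo) * (y_hi - y_lo)

    @property
    def leader_ids(self) -> list[int]:
        return [l for e in self.explants for l in e.leader_ids]


def build_substrate(lattice_dims: tuple[int, int, int]) -> SimState:
    """A fresh state: immutable substrate plane at z = 0, medium above."""
    return SimState(lattice_dims)


def build_dmz(state: SimState, spec: ExplantSpec, config: SimConfig,
              rng: np.random.Generator) -> ExplantInfo:
    """Place one DMZ explant and wire up its initial links.

    Creates width x length x height cells of ``voxels_per_cell_edge**3``
    voxels each; assigns leaders per ``config.leader_rows`` ("bottom":
    the bottom-layer leading row; "full_face": the whole leading face);
    links every grid-adjacent cell pair with a cell-cell spring; anchors
    bottom-layer followers to the substrate beneath their centroids; and
    gives each leader an initial lamellipodium through a uniformly random
    free-edge voxel (no cohesotaxis bias at initialization) to set an
    initial forward direction.
    """
    lead_il = spec.length_cells - 1
    grid_to_id: dict[tuple[int, int, int], int] = {}
    for ih in range(spec.height_cells):
        for il in range(spec.length_cells):
            for iw in range(spec.width_cells):
                is_leader = (il == lead_il and
                             (ih == 0 or config.leader_rows == "full_face"))
                ctype = CellType.LEADER if is_leader else CellType.FOLLOWER
                cid = state.add_cell(spec.cell_block(iw, il, ih), ctype)
                grid_to_id[(iw, il, ih)] = cid
    # cell-cell springs between all grid-adjacent pairs
    for (iw, il, ih), cid in grid_to_id.items():
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (iw + d[0], il + d[1], ih + d[2])
            if nb in grid_to_id:
                state.links.add(LinkKind.CELL_CELL, cid, grid_to_id[nb],
                                lam=config.lambda_tissue,
                                target_length=config.link_target_length)
    # follower-substrate springs for the bottom layer
    for (iw, il, ih), cid in grid_to_id.items():
        if ih == 0 and state.cell_type[cid] == int(CellType.FOLLOWER):
            c = state.centroid(cid)
            state.links.add(LinkKind.FOLLOWER_SUBSTRATE, cid,
                            anchor=(c[0], c[1], 0.0),
                            lam=config.lambda_follower_substrate,
                            target_length=config.substrate_link_target_length)
    # initial lamellipodia
    leader_ids = []
    for iw in range(spec.width_cells):
        for ih in range(spec.height_cells):
            cid = grid_to_id.get((iw, lead_il, ih))
            if cid is not None and state.cell_type[cid] == int(CellType.LEADER):
                leader_ids.append(cid)
    for cid in leader_ids:
        free = free_edge_voxels(state, cid)
        if len(free):
            voxel = free[rng.integers(len(free))]
            place_lamellipodium(state, cid, voxel, config)
    n = len(leader_ids)
    center = leader_ids[n // 2 - 2:n // 2 + 2] if n >= 4 else list(leader_ids)
    return ExplantInfo(facing=spec.facing, axis=_FACING_AXES[spec.facing].copy(),
                       cell_ids=sorted(grid_to_id.values()),
                       leader_ids=leader_ids, center_leader_ids=center)


def dmz_lattice_dims(spec_kw: dict | None = None, forward_margin: int = 60,
                     back_margin: int = 8, side_margin: int = 6,
                     top_margin: int = 4) -> tuple[int, int, int]:
    kw = {"width_cells": 8, "length_cells": 4, "height_cells": 2,
          "voxels_per_cell_edge": 5}
    kw.update(spec_kw or {})
    e = kw["voxels_per_cell_edge"]
    X = back_margin + kw["length_cells"] * e + forward_margin
    Y = 2 * side_margin + kw["width_cells"] * e
    Z = 1 + kw["height_cells"] * e + top_margin
    return (X, Y, Z)


def make_dmz_state(config: SimConfig, rng: np.random.Generator,
                   forward_margin: int = 60, back_margin: int = 8,
                   side_margin: int = 6, top_margin: int = 4,
                   **spec_kw) -> tuple[SimState, ExplantInfo]:
    """Substrate + one +x-facing DMZ explant with free migration room of
    at least twice the explant length ahead of the leading edge."""
    dims = dmz_lattice_dims(spec_kw, forward_margin, back_margin,
                            side_margin, top_margin)
    state = build_substrate(dims)
    spec = ExplantSpec(origin=(back_margin, side_margin), facing="+x",
                       **spec_kw)
    info = build_dmz(state, spec, config, rng)
    return state, info


def build_itr(config: SimConfig, rng: np.random.Generator,
              margin: int = 6, top_margin: int = 4,
              **spec_kw) -> tuple[SimState, ITRInfo]:
    """Four DMZ explants facing +x, +y, -x, -y around a central cell-free
    square of side ``config.itr_gap`` voxels.

    The lattice is square in-plane so the four placements are exact
    90-degree rotations of one another about the gap center; no model
    parameter differs from the single-explant configuration.
    """
    kw = {"width_cells": 8, "length_cells": 4, "height_cells": 2,
          "voxels_per_cell_edge": 5}
    kw.update(spec_kw)
    e = kw["voxels_per_cell_edge"]
    length = kw["length_cells"] * e
    width = kw["width_cells"] * e
    g = int(config.itr_gap)
    S = 2 * margin + 2 * length + g
    Z = 1 + kw["height_cells"] * e + top_margin
    state = build_substrate((S, S, Z))
    lo = margin + length          # gap low edge
    hi = lo + g                   # gap high edge (exclusive)
    cw = (S - width) // 2         # centered width placement
    specs = [
        ExplantSpec(origin=(margin, cw), facing="+x", **kw),
        ExplantSpec(origin=(cw, margin), facing="+y", **kw),
        ExplantSpec(origin=(hi, cw), facing="-x", **kw),
        ExplantSpec(origin=(cw, hi), facing="-y", **kw),
    ]
    infos = [build_dmz(state, s, config, rng) for s in specs]
    return state, ITRInfo(explants=infos, gap_bounds=(lo, hi, lo, hi))
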