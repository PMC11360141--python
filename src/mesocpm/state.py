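"""Lattice state and cell agents.

The simulation state is a 3D integer owner lattice plus per-cell
bookkeeping arrays (type, volume, coordinate sums for O(1) centroids) and
the mechanical-link registry.  Owner codes: ``0`` medium, ``-1`` substrate
(a single immutable plane at ``z == 0``), ``> 0`` cell IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .config import LEADER, FOLLOWER

MEDIUM_ID = 0
SUBSTRATE_ID = -1


class CellType(IntEnum):
    """Agent type codes (match the contact-energy matrix indices)."""

    LEADER = LEADER
    FOLLOWER = FOLLOWER


@dataclass
class CellAgent:
    """Read-only view of one cell agent, materialized on demand."""

    id: int
    type: CellType
    volume: int
    centroid: np.ndarray
    voxels: np.ndarray  # (V, 3) int coordinates
    links: frozenset  # link IDs attached to this cell


class SimState:
    """Mutable simulation state: owner lattice + cell registry + links."""

    def __init__(self, dims: tuple[int, int, int]):
        X, Y, Z = dims
        if X < 3 or Y < 3 or Z < 3:
            raise ValueError("lattice dims must each be >= 3")
        self.owner = np.zeros((X, Y, Z), dtype=np.int32)
        self.owner[:, :, 0] = SUBSTRATE_ID
        # index 0 unused so arrays are indexed directly by cell ID
        self.cell_type = np.zeros(1, dtype=np.int8)
        self.volume = np.zeros(1, dtype=np.int64)
        self.sum_x = np.zeros(1, dtype=np.int64)
        self.sum_y = np.zeros(1, dtype=np.int64)
        self.sum_z = np.zeros(1, dtype=np.int64)
        self.alive = np.zeros(1, dtype=bool)
        self.mcs = 0
        self.lamellipodia_blocked = False
        self.removed_cells: list[tuple[int, int]] = []  # (cell_id, mcs)
        from .links import LinkRegistry  # local import avoids a cycle

        self.links = LinkRegistry()

    # -- construction -----------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int]:
        return self.owner.shape

    @property
    def n_cells(self) -> int:
        return len(self.volume) - 1

    def cell_ids(self, alive_only: bool = True) -> np.ndarray:
        ids = np.arange(1, len(self.volume))
        return ids[self.alive[1:]] if alive_only else ids

    def add_cell(self, voxels: np.ndarray, ctype: CellType) -> int:
        """Claim ``voxels`` (must currently be medium) for a new cell."""
        voxels = np.asarray(voxels, dtype=np.int64)
        if voxels.ndim != 2 or voxels.shape[1] != 3 or len(voxels) == 0:
            raise ValueError("voxels must be a nonempty (V, 3) array")
        xs, ys, zs = voxels[:, 0], voxels[:, 1], voxels[:, 2]
        if np.any(self.owner[xs, ys, zs] != MEDIUM_ID):
            raise ValueError("cell voxels overlap existing non-medium voxels")
        cid = len(self.volume)
        self.owner[xs, ys, zs] = cid
        self.cell_type = np.append(self.cell_type, np.int8(ctype))
        self.volume = np.append(self.volume, len(voxels))
        self.sum_x = np.append(self.sum_x, xs.sum())
        self.sum_y = np.append(self.sum_y, ys.sum())
        self.sum_z = np.append(self.sum_z, zs.sum())
        self.alive = np.append(self.alive, True)
        return cid

    # -- queries ----------------------------------------------------------
    def centroid(self, cid: int) -> np.ndarray:
        v = self.volume[cid]
        if v == 0:
            raise ValueError(f"cell {cid} has zero volume")
        return np.array([self.sum_x[cid], self.sum_y[cid], self.sum_z[cid]],
                        dtype=np.float64) / v

    def centroids(self, cids) -> np.ndarray:
        cids = np.asarray(cids)
        v = self.volume[cids].astype(np.float64)
        return np.stack([self.sum_x[cids], self.sum_y[cids],
                         self.sum_z[cids]], axis=1) / v[:, None]

    def cell_voxels(self, cid: int) -> np.ndarray:
        # fast path: scan a bounding box around the centroid; fall back to
        # a full-lattice scan if the cell extends beyond it
        v = int(self.volume[cid])
        if v > 0:
            c = self.centroid(cid)
            margin = 8
            lo = np.maximum(np.floor(c).astype(np.int64) - margin, 0)
            hi = np.minimum(np.ceil(c).astype(np.int64) + margin + 1,
                            np.array(self.dims))
            box = self.owner[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            vox = np.argwhere(box == cid)
            if len(vox) == v:
                return vox + lo
        return np.argwhere(self.owner == cid)

    def cell(self, cid: int) -> CellAgent:
        return CellAgent(
            id=cid,
            type=CellType(int(self.cell_type[cid])),
            volume=int(self.volume[cid]),
            centroid=self.centroid(cid),
            voxels=self.cell_voxels(cid),
            links=frozenset(self.links.ids_of(cid)),
        )

    def substrate_plane_ids(self) -> np.ndarray:
        """Cell IDs owning >= 1 voxel in the layer touching the substrate."""
        ids = np.unique(self.owner[:, :, 1])
        return ids[ids > 0]

    # -- maintenance ------------------------------------------------------
    def remove_dead_cells(self) -> list[int]:
        """Drop cells whose volume reached 0 (and their links)."""
        dead = [int(c) for c in self.cell_ids() if self.volume[c] == 0]
        for cid in dead:
            self.alive[cid] = False
            self.links.remove_links_of(cid)
            self.removed_cells.append((cid, self.mcs))
        return dead

    def check_consistency(self) -> None:
        """Hard-fail if bookkeeping disagrees with the lattice."""
        if not np.all(self.owner[:, :, 0] == SUBSTRATE_ID):
            raise AssertionError("substrate plane corrupted")
        if np.any(self.owner[:, :, 1:] == SUBSTRATE_ID):
            raise AssertionError("substrate voxels outside z=0")
        for cid in self.cell_ids():
            vox = self.cell_voxels(cid)
            if len(vox) != self.volume[cid]:
                raise AssertionError(
                    f"cell {cid}: volume {self.volume[cid]} != |voxels| {len(vox)}")
            sums = vox.sum(axis=0)
            if not (sums[0] == self.sum_x[cid] and sums[1] == self.sum_y[cid]
                    and sums[2] == self.sum_z[cid]):
                raise AssertionError(f"cell {cid}: centroid sums out of date")
        owned = set(np.unique(self.owner))
        owned -= {MEDIUM_ID, SUBSTRATE_ID}
        if owned != set(int(c) for c in self.cell_ids()):
            raise AssertionError("lattice owners disagree with cell registry")

    def copy(self) -> "SimState":
        import copy as _copy

        new = SimState.__new__(SimState)
        new.owner = self.owner.copy()
        for name in ("cell_type", "volume", "sum_x", "sum_y", "sum_z", "alive"):
            setattr(new, name, getattr(self, name).copy())
        new.mcs = self.mcs
        new.lamellipodia_blocked = self.lamellipodia_blocked
        new.removed_cells = list(self.removed_cells)
        new.links = _copy.deepcopy(self.links)
        return new
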