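"""Mechanical link objects and their turnover.

Three kinds of link transmit force between cell centroids and the world:

* ``CELL_CELL`` — Hookean spring between the centroids of two cells,
  energy ``lambda * (l - L)**2``; represents junctional cell-cell adhesion.
* ``FOLLOWER_SUBSTRATE`` — Hookean spring from a follower centroid to a
  fixed anchor on the substrate plane.
* ``LAMELLIPODIUM`` — constant-tension element from a leader centroid to a
  substrate anchor, energy ``lambda * l`` (length-independent force);
  represents protrusive traction.  A lamellipodium whose leader has pulled
  its centroid within reach of the anchor is "satisfied" and exerts no
  further force until turnover replaces it.

Extension-retraction is a Poisson process: each timestep a link of rate
``zeta`` is deleted-and-reformed with probability ``1 - exp(-zeta)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .config import SimConfig
from .state import SimState, CellType

logger = logging.getLogger(__name__)


class LinkKind(IntEnum):
    CELL_CELL = 0
    FOLLOWER_SUBSTRATE = 1
    LAMELLIPODIUM = 2


@dataclass
class Link:
    id: int
    kind: LinkKind
    cell_a: int
    cell_b: int | None = None          # partner cell (CELL_CELL only)
    anchor: np.ndarray | None = None   # substrate anchor (other kinds)
    lam: float = 0.0
    target_length: float = 0.0         # unused for LAMELLIPODIUM
    age: int = 0
    satisfied: bool = False            # LAMELLIPODIUM reach flag

    def endpoints(self) -> tuple[int, int | None]:
        return self.cell_a, self.cell_b


class LinkRegistry:
    """All live links, indexed by ID and by attached cell."""

    def __init__(self):
        self._links: dict[int, Link] = {}
        self._by_cell: dict[int, set[int]] = {}
        self._next_id = 1

    def __len__(self) -> int:
        return len(self._links)

    def __iter__(self):
        return iter(self._links.values())

    def __contains__(self, link_id: int) -> bool:
        return link_id in self._links

    def get(self, link_id: int) -> Link:
        return self._links[link_id]

    def ids_of(self, cid: int) -> set[int]:
        return set(self._by_cell.get(cid, ()))

    def links_of(self, cid: int, kind: LinkKind | None = None) -> list[Link]:
        out = [self._links[i] for i in sorted(self._by_cell.get(cid, ()))]
        if kind is not None:
            out = [l for l in out if l.kind == kind]
        return out

    def of_kind(self, kind: LinkKind) -> list[Link]:
        return [l for i, l in sorted(self._links.items()) if l.kind == kind]

    def cellcell_degree(self, cid: int) -> int:
        return sum(1 for l in self.links_of(cid) if l.kind == LinkKind.CELL_CELL)

    def has_cellcell(self, a: int, b: int) -> bool:
        for i in self._by_cell.get(a, ()):
            l = self._links[i]
            if l.kind == LinkKind.CELL_CELL and {l.cell_a, l.cell_b} == {a, b}:
                return True
        return False

    def add(self, kind: LinkKind, cell_a: int, cell_b: int | None = None,
            anchor=None, lam: float = 0.0, target_length: float = 0.0) -> Link:
        if kind == LinkKind.CELL_CELL:
            if cell_b is None or cell_b == cell_a:
                raise ValueError("CELL_CELL link needs two distinct cells")
            if self.has_cellcell(cell_a, cell_b):
                raise ValueError(f"duplicate cell-cell link {cell_a}-{cell_b}")
        else:
            if anchor is None:
                raise ValueError(f"{kind.name} link needs a substrate anchor")
            anchor = np.asarray(anchor, dtype=np.float64)
        link = Link(id=self._next_id, kind=kind, cell_a=cell_a, cell_b=cell_b,
                    anchor=anchor, lam=lam, target_length=target_length)
        self._next_id += 1
        self._links[link.id] = link
        self._by_cell.setdefault(cell_a, set()).add(link.id)
        if cell_b is not None:
            self._by_cell.setdefault(cell_b, set()).add(link.id)
        return link

    def remove(self, link_id: int) -> None:
        link = self._links.pop(link_id)
        for c in (link.cell_a, link.cell_b):
            if c is not None:
                self._by_cell[c].discard(link_id)

    def remove_links_of(self, cid: int) -> None:
        for i in list(self._by_cell.get(cid, ())):
            self.remove(i)

    def age_all(self) -> None:
        for l in self._links.values():
            l.age += 1

    # -- kernel interface -------------------------------------------------
    def flatten(self, n_cells: int):
        """Pack links into flat arrays + a per-cell CSR index for the
        Monte-Carlo kernel."""
        n = len(self._links)
        kind = np.zeros(n, dtype=np.int8)
        ca = np.zeros(n, dtype=np.int32)
        cb = np.full(n, -1, dtype=np.int32)
        ax = np.zeros(n, dtype=np.float64)
        ay = np.zeros(n, dtype=np.float64)
        az = np.zeros(n, dtype=np.float64)
        lam = np.zeros(n, dtype=np.float64)
        L0 = np.zeros(n, dtype=np.float64)
        sat = np.zeros(n, dtype=np.uint8)
        counts = np.zeros(n_cells + 2, dtype=np.int64)
        for row, (_, l) in enumerate(sorted(self._links.items())):
            kind[row] = int(l.kind)
            ca[row] = l.cell_a
            counts[l.cell_a + 1] += 1
            if l.cell_b is not None:
                cb[row] = l.cell_b
                counts[l.cell_b + 1] += 1
            else:
                ax[row], ay[row], az[row] = l.anchor
            lam[row] = l.lam
            L0[row] = l.target_length
            sat[row] = 1 if l.satisfied else 0
        ptr = np.cumsum(counts)
        lidx = np.zeros(ptr[-1], dtype=np.int64)
        fill = ptr[:-1].copy()
        for row in range(n):
            lidx[fill[ca[row]]] = row
            fill[ca[row]] += 1
            if cb[row] >= 0:
                lidx[fill[cb[row]]] = row
                fill[cb[row]] += 1
        return ptr, lidx, kind, ca, cb, ax, ay, az, lam, L0, sat


# ---------------------------------------------------------------------------
# energies

def elastic_energy(link: Link, centroid_a, centroid_or_anchor_b) -> float:
    """Hookean energy ``lambda * (l - L)**2`` of a spring-like link."""
    if link.kind == LinkKind.LAMELLIPODIUM:
        raise ValueError("elastic_energy applies to spring-like links only")
    l = float(np.linalg.norm(np.asarray(centroid_a, dtype=float)
                             - np.asarray(centroid_or_anchor_b, dtype=float)))
    return link.lam * (l - link.target_length) ** 2


def tension_energy(link: Link, centroid, anchor) -> float:
    """Constant-tension energy ``lambda * l``; zero once satisfied.

    Linear energy in length means the force magnitude ``dE/dl`` equals
    ``lambda`` independent of length (a stalling-force-like traction).
    """
    if link.kind != LinkKind.LAMELLIPODIUM:
        raise ValueError("tension_energy applies to lamellipodium links only")
    if link.satisfied:
        return 0.0
    l = float(np.linalg.norm(np.asarray(centroid, dtype=float)
                             - np.asarray(anchor, dtype=float)))
    return link.lam * l


def link_energy(link: Link, state: SimState) -> float:
    pa = state.centroid(link.cell_a)
    if link.kind == LinkKind.CELL_CELL:
        return elastic_energy(link, pa, state.centroid(link.cell_b))
    if link.kind == LinkKind.FOLLOWER_SUBSTRATE:
        return elastic_energy(link, pa, link.anchor)
    return tension_energy(link, pa, link.anchor)


# ---------------------------------------------------------------------------
# Poisson turnover

def turnover_probability(zeta: float) -> float:
    if zeta < 0:
        raise ValueError("Poisson rate zeta must be >= 0")
    return 1.0 - math.exp(-zeta)


def turnover_fires(zeta: float, rng: np.random.Generator) -> bool:
    """One Bernoulli draw of the per-timestep Poisson event probability
    ``P = 1 - exp(-zeta * dt)`` with ``dt = 1`` timestep."""
    p = turnover_probability(zeta)
    return bool(rng.random() < p) if p > 0 else False


# ---------------------------------------------------------------------------
# lamellipodium lifecycle (leaders)

def _clamp_anchor(x: float, y: float, dims) -> tuple[float, float, bool]:
    X, Y, _ = dims
    cx = min(max(x, 0.0), X - 1.0)
    cy = min(max(y, 0.0), Y - 1.0)
    return cx, cy, (cx != x or cy != y)


def place_lamellipodium(state: SimState, leader_id: int, direction_voxel,
                        config: SimConfig) -> Link:
    """Create a lamellipodium link whose substrate anchor lies
    ``chi_lamellipodia`` beyond ``direction_voxel`` along the in-plane
    centroid-to-voxel direction."""
    c = state.centroid(leader_id)
    v = np.asarray(direction_voxel, dtype=np.float64)
    d = v[:2] - c[:2]
    norm = float(np.hypot(d[0], d[1]))
    if norm < 1e-9:
        # voxel directly above/below the centroid: no in-plane direction;
        # anchor straight at the voxel's footprint
        d = np.zeros(2)
    else:
        d /= norm
    ax = v[0] + config.chi_lamellipodia * d[0]
    ay = v[1] + config.chi_lamellipodia * d[1]
    ax, ay, clamped = _clamp_anchor(ax, ay, state.dims)
    if clamped:
        logger.debug("lamellipodium anchor clamped to lattice bounds "
                     "(leader %d)", leader_id)
    return state.links.add(LinkKind.LAMELLIPODIUM, leader_id,
                           anchor=(ax, ay, 0.0),
                           lam=config.lambda_lamellipodia)


def cycle_lamellipodium(state: SimState, leader_id: int, config: SimConfig,
                        rng: np.random.Generator) -> Link | None:
    """Poisson extension-retraction of a leader's lamellipodium.

    On firing, the existing link (if any) is deleted and — unless
    lamellipodium formation is blocked or the leader has no free edge —
    a new one is created through a cohesotaxis-selected free-edge voxel.
    A leader fully surrounded by other cells forms nothing and behaves
    as a follower until an edge frees up.
    """
    from .cohesotaxis import free_edge_voxels, select_direction_voxel

    if state.cell_type[leader_id] != int(CellType.LEADER):
        raise ValueError(f"cell {leader_id} is not a leader")
    if not turnover_fires(config.zeta_lamellipodia, rng):
        return None
    for l in state.links.links_of(leader_id, LinkKind.LAMELLIPODIUM):
        state.links.remove(l.id)
    if state.lamellipodia_blocked:
        return None
    vox = state.cell_voxels(leader_id)
    free = free_edge_voxels(state, leader_id, voxels=vox)
    if len(free) == 0:
        return None
    voxel = select_direction_voxel(state, leader_id, config.kappa, rng,
                                   bias_toward=config.bias_toward,
                                   free_edges=free, voxels=vox)
    return place_lamellipodium(state, leader_id, voxel, config)


def mark_satisfied(link: Link, centroid, tolerance: float = 1.0) -> Link:
    """Flag a lamellipodium as reached once the in-plane centroid-anchor
    distance falls within ``tolerance`` voxels.  Sticky until turnover."""
    if link.kind != LinkKind.LAMELLIPODIUM:
        raise ValueError("mark_satisfied applies to lamellipodium links only")
    if link.satisfied:
        return link
    c = np.asarray(centroid, dtype=float)
    d = float(np.hypot(c[0] - link.anchor[0], c[1] - link.anchor[1]))
    if d <= tolerance:
        link.satisfied = True
    return link


def update_satisfied(state: SimState, config: SimConfig) -> None:
    for link in state.links.of_kind(LinkKind.LAMELLIPODIUM):
        mark_satisfied(link, state.centroid(link.cell_a),
                       config.lamellipodium_reach_tolerance)


# ---------------------------------------------------------------------------
# follower-substrate lifecycle

def follower_touches_substrate(state: SimState, cid: int,
                               plane_ids=None) -> bool:
    if plane_ids is not None:
        return cid in plane_ids
    return bool(np.any(state.owner[:, :, 1] == cid))


def cycle_follower_substrate(state: SimState, follower_id: int,
                             config: SimConfig, rng: np.random.Generator,
                             plane_ids=None) -> Link | None:
    """Maintain a follower's single substrate spring.

    Only followers with >= 1 voxel adjacent to the substrate plane hold a
    link; on Poisson firing the link re-anchors directly beneath the
    current centroid (the cell "re-grips" the substrate under itself).
    """
    if state.cell_type[follower_id] != int(CellType.FOLLOWER):
        raise ValueError(f"cell {follower_id} is not a follower")
    existing = state.links.links_of(follower_id, LinkKind.FOLLOWER_SUBSTRATE)
    touching = follower_touches_substrate(state, follower_id, plane_ids)
    if not touching:
        for l in existing:
            state.links.remove(l.id)
        return None
    c = state.centroid(follower_id)
    if not existing:
        return state.links.add(
            LinkKind.FOLLOWER_SUBSTRATE, follower_id,
            anchor=(c[0], c[1], 0.0),
            lam=config.lambda_follower_substrate,
            target_length=config.substrate_link_target_length)
    if turnover_fires(config.zeta_substrate, rng):
        link = existing[0]
        state.links.remove(link.id)
        return state.links.add(
            LinkKind.FOLLOWER_SUBSTRATE, follower_id,
            anchor=(c[0], c[1], 0.0),
            lam=config.lambda_follower_substrate,
            target_length=config.substrate_link_target_length)
    return None
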