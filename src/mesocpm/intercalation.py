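"""Stochastic cell-cell link turnover enabling passive intercalation.

Each cell-cell adhesion link carries a Poisson lifetime with rate
``zeta_tissue`` per timestep.  When a link breaks, the breaking cell forms
a new link to a uniformly random lattice-adjacent neighbor it is not yet
linked to, subject to a cap of ``max_reformed_neighbors`` (default 4)
cell-cell links.  Re-linking to new neighbors lets cells slip past one
another, and in a multilayer explant produces radial (top-down)
intercalation: upper-layer cells work their way onto the substrate and
the tissue flattens.  ``zeta_tissue = 0`` disables the rule entirely.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .links import LinkKind, LinkRegistry, turnover_probability
from .state import SimState

_SHIFTS = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


def cell_adjacency(state: SimState) -> dict[int, set[int]]:
    """Face-contact adjacency between cells, from the owner lattice."""
    adj: dict[int, set[int]] = {int(c): set() for c in state.cell_ids()}
    owner = state.owner
    X, Y, Z = state.dims
    for dx, dy, dz in _SHIFTS:
        a = owner[:X - dx, :Y - dy, :Z - dz]
        b = owner[dx:, dy:, dz:]
        mask = (a != b) & (a > 0) & (b > 0)
        if not mask.any():
            continue
        pairs = np.unique(
            np.stack([a[mask], b[mask]], axis=1), axis=0)
        for p, q in pairs:
            adj[int(p)].add(int(q))
            adj[int(q)].add(int(p))
    return adj


def maybe_break_cell_links(links: LinkRegistry, zeta_tissue: float,
                           rng: np.random.Generator) -> set[int]:
    """Independently break each cell-cell link with P = 1 - exp(-zeta)."""
    p = turnover_probability(zeta_tissue)
    if p == 0:
        return set()
    cc = links.of_kind(LinkKind.CELL_CELL)
    if not cc:
        return set()
    draws = rng.random(len(cc))
    return {l.id for l, u in zip(cc, draws) if u < p}


def reform_link(state: SimState, cell: int, candidate_neighbors,
                max_neighbors: int, rng: np.random.Generator,
                config: SimConfig):
    """Form one new cell-cell link from ``cell`` to a uniformly random
    eligible neighbor, or ``None`` if the cell is at its cap or has no
    eligible neighbor.  Eligible neighbors are lattice-adjacent, not
    already linked to ``cell``, and themselves below the cap."""
    links = state.links
    if links.cellcell_degree(cell) >= max_neighbors:
        return None
    eligible = sorted(
        n for n in candidate_neighbors
        if n != cell and not links.has_cellcell(cell, n)
        and links.cellcell_degree(n) < max_neighbors)
    if not eligible:
        return None
    partner = eligible[rng.integers(len(eligible))]
    return links.add(LinkKind.CELL_CELL, cell, partner,
                     lam=config.lambda_tissue,
                     target_length=config.link_target_length)


def intercalation_step(state: SimState, config: SimConfig,
                       rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """One timestep of break-then-reform turnover; returns an event log of
    ``(event, cell_id, partner_id)`` tuples."""
    broken = maybe_break_cell_links(state.links, config.zeta_tissue, rng)
    if not broken:
        return []
    events: list[tuple[str, int, int]] = []
    reformers: list[int] = []
    for lid in sorted(broken):
        link = state.links.get(lid)
        a, b = link.cell_a, link.cell_b
        # the "breaking cell" that re-links is drawn at random between
        # the two endpoints
        reformers.append(a if rng.random() < 0.5 else b)
        events.append(("break", a, b))
        state.links.remove(lid)
    adj = cell_adjacency(state)
    for cell in reformers:
        if not state.alive[cell]:
            continue
        new = reform_link(state, cell, adj.get(cell, ()),
                          config.max_reformed_neighbors, rng, config)
        if new is not None:
            events.append(("reform", new.cell_a, new.cell_b))
    return events
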