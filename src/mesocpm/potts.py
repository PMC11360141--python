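"""The Cellular-Potts engine.

The effective energy of a configuration is

    H = sum_neighbors J(tau_i, tau_j) * [sigma_i != sigma_j]
      + sum_cells lambda_volume * (V_cell - V_target)**2
      + sum_links E_link,

where the contact sum runs over 26-neighborhood lattice-site pairs with
unequal owners and the link energies are defined in :mod:`mesocpm.links`.
One Monte-Carlo step (MCS) performs N voxel-copy attempts (N = number of
non-substrate sites): a random site copies its owner onto a random
6-neighbor with the Boltzmann acceptance

    P(accept) = 1                   if dH <= 0
              = exp(-dH / T)        otherwise,

then runs per-timestep link turnover and intercalation.  1 MCS represents
5 s of real time.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .config import SimConfig
from .links import (LinkKind, link_energy, cycle_lamellipodium,
                    cycle_follower_substrate, update_satisfied)
from .state import SimState, CellType, MEDIUM_ID, SUBSTRATE_ID

_HALF_NEIGHBORHOOD = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def _type_grid(state: SimState) -> np.ndarray:
    """Per-voxel type code grid (0 medium, 1 substrate, 2 leader, 3 follower)."""
    t = np.zeros(state.dims, dtype=np.int8)
    t[state.owner == SUBSTRATE_ID] = 1
    for cid in state.cell_ids():
        t[state.owner == cid] = state.cell_type[cid]
    return t


def compute_total_energy(state: SimState, config: SimConfig) -> float:
    """Full recomputation of H; used for initialization and as the slow
    reference path for the incremental kernel."""
    for cid in state.cell_ids():
        if state.volume[cid] != np.count_nonzero(state.owner == cid):
            raise AssertionError(f"inconsistent state: cell {cid} volume")
    J = config.contact_energy.as_matrix()
    types = _type_grid(state)
    owner = state.owner
    contact = 0.0
    for dx, dy, dz in _HALF_NEIGHBORHOOD:
        X, Y, Z = state.dims
        a = owner[max(0, -dx):X - max(0, dx),
                  max(0, -dy):Y - max(0, dy),
                  max(0, -dz):Z - max(0, dz)]
        b = owner[max(0, dx):X - max(0, -dx),
                  max(0, dy):Y - max(0, -dy),
                  max(0, dz):Z - max(0, -dz)]
        ta = types[max(0, -dx):X - max(0, dx),
                   max(0, -dy):Y - max(0, dy),
                   max(0, -dz):Z - max(0, dz)]
        tb = types[max(0, dx):X - max(0, -dx),
                   max(0, dy):Y - max(0, -dy),
                   max(0, dz):Z - max(0, -dz)]
        mask = a != b
        contact += J[ta[mask], tb[mask]].sum()
    vols = state.volume[state.cell_ids()]
    volume_term = config.lambda_volume * ((vols - config.v_target) ** 2).sum()
    link_term = sum(link_energy(l, state) for l in state.links)
    return float(contact + volume_term + link_term)


def acceptance_probability(delta_h: float, temperature: float) -> float:
    """Boltzmann acceptance: 1 for dH <= 0, exp(-dH/T) otherwise."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_h <= 0:
        return 1.0
    return math.exp(-delta_h / temperature)


def delta_energy(state: SimState, config: SimConfig,
                 source_voxel, target_voxel) -> float:
    """Incremental dH of copying the source voxel's owner onto the target
    voxel, without mutating the state.

    Source and target must be 6-neighbors with different owners; attempts
    involving the substrate are rejected before evaluation.
    """
    s = tuple(int(v) for v in source_voxel)
    t = tuple(int(v) for v in target_voxel)
    if sum(abs(a - b) for a, b in zip(s, t)) != 1:
        raise ValueError("source and target must be face neighbors")
    o_s = int(state.owner[s])
    o_t = int(state.owner[t])
    if o_s == SUBSTRATE_ID or o_t == SUBSTRATE_ID:
        raise ValueError("voxel copies may not involve the substrate")
    if o_s == o_t:
        raise ValueError("source and target already share an owner")
    flat = state.links.flatten(state.n_cells)
    return float(_kernels.delta_H(
        state.owner, config.contact_energy.as_matrix(),
        state.cell_type, state.volume,
        state.sum_x, state.sum_y, state.sum_z,
        float(config.lambda_volume), int(config.v_target),
        *flat, t[0], t[1], t[2], o_s, o_t))


def monte_carlo_step(state: SimState, config: SimConfig,
                     rng: np.random.Generator) -> int:
    """Advance the simulation by one MCS (one timestep, 5 s).

    Performs N voxel-copy attempts with N = number of non-substrate
    lattice sites, prunes cells that reached volume 0, updates
    lamellipodium reach flags, then executes Poisson link turnover for
    leaders and followers and the intercalation break/reform step.
    Returns the number of accepted copies.
    """
    from .intercalation import intercalation_step

    X, Y, Z = state.dims
    n_sites = X * Y * (Z - 1)
    sites = rng.integers(0, n_sites, size=n_sites, dtype=np.int64)
    dirs = rng.integers(0, 6, size=n_sites, dtype=np.int8)
    unifs = rng.random(n_sites, dtype=np.float32)
    flat = state.links.flatten(state.n_cells)
    accepted = _kernels.run_sweep(
        state.owner, config.contact_matrix(),
        state.cell_type, state.volume,
        state.sum_x, state.sum_y, state.sum_z,
        float(config.lambda_volume), int(config.v_target),
        float(config.temperature), *flat, sites, dirs, unifs)
    state.remove_dead_cells()
    update_satisfied(state, config)
    plane_ids = set(int(c) for c in state.substrate_plane_ids())
    for cid in state.cell_ids():
        if state.cell_type[cid] == int(CellType.LEADER):
            cycle_lamellipodium(state, int(cid), config, rng)
        else:
            cycle_follower_substrate(state, int(cid), config, rng,
                                     plane_ids=plane_ids)
    intercalation_step(state, config, rng)
    state.links.age_all()
    state.mcs += 1
    return int(accepted)
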