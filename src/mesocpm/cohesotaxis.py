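"""Cohesotaxis: a direction-agnostic protrusion bias for leader cells.

Adherent cells in a collective polarize away from sites of cell-cell
adhesion, protruding at the free leading edge.  The model encodes this by
ranking a leader's free-edge voxels (voxels touching medium) by their
cumulative Euclidean distance to the cell's cell-cell border voxels, then
sampling a direction voxel through a normalized sigmoid weight vector.

The weights come from a logistic curve ``f(x) = 1 / (1 + exp(-s x))`` with
steepness ``s = 2**kappa`` evaluated at ``n`` evenly spaced points across a
fixed viewing window ``[-5, 5]`` and normalized to sum to 1, so the same
bias shape applies no matter how many free-edge voxels the cell currently
has.  ``kappa = -6`` is near-uniform (no migratory bias); ``kappa = +6``
approaches a step that concentrates all mass on the voxels farthest from
cell-cell contacts — the forward direction of a leading-row cell.  Because
the ranking is relative to the cell's own contacts, the bias works
whichever way the explant faces.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .state import SimState, MEDIUM_ID

_FACE_OFFSETS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                          [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64)


def _face_neighbor_owners(state: SimState, voxels: np.ndarray) -> np.ndarray:
    """Owners of the 6 face neighbors of each voxel; out-of-lattice
    neighbors read as an impossible code (-2, neither medium nor cell)."""
    X, Y, Z = state.dims
    out = np.full((len(voxels), 6), -2, dtype=np.int64)
    for k, off in enumerate(_FACE_OFFSETS):
        nb = voxels + off
        ok = ((nb[:, 0] >= 0) & (nb[:, 0] < X) & (nb[:, 1] >= 0)
              & (nb[:, 1] < Y) & (nb[:, 2] >= 0) & (nb[:, 2] < Z))
        out[ok, k] = state.owner[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
    return out


def _lexsorted(voxels: np.ndarray) -> np.ndarray:
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    return voxels[order]


def free_edge_voxels(state: SimState, cid: int,
                     voxels: np.ndarray | None = None) -> np.ndarray:
    """The cell's voxels with >= 1 face neighbor owned by medium, in
    lexicographic order.  Empty for a fully enclosed cell."""
    if voxels is None:
        voxels = state.cell_voxels(cid)
    if len(voxels) == 0:
        return voxels.reshape(0, 3)
    nb = _face_neighbor_owners(state, voxels)
    mask = np.any(nb == MEDIUM_ID, axis=1)
    return _lexsorted(voxels[mask])


def cell_border_voxels(state: SimState, cid: int,
                       voxels: np.ndarray | None = None) -> np.ndarray:
    """The cell's voxels with >= 1 face neighbor owned by a *different
    cell* (medium and substrate excluded), in lexicographic order."""
    if voxels is None:
        voxels = state.cell_voxels(cid)
    if len(voxels) == 0:
        return voxels.reshape(0, 3)
    nb = _face_neighbor_owners(state, voxels)
    mask = np.any((nb > 0) & (nb != cid), axis=1)
    return _lexsorted(voxels[mask])


def cumulative_border_distance(voxel, border_voxels: np.ndarray) -> float:
    """Sum of Euclidean distances from ``voxel`` to every border voxel;
    0 when the border set is empty (uniform ranking fallback)."""
    border_voxels = np.asarray(border_voxels, dtype=np.float64)
    if len(border_voxels) == 0:
        return 0.0
    d = border_voxels - np.asarray(voxel, dtype=np.float64)
    return float(np.sqrt((d * d).sum(axis=1)).sum())


def bias_weights(n: int, kappa: float) -> np.ndarray:
    """Normalized sigmoid probability weights over a sorted list of ``n``
    voxels.

    The logistic ``f(x) = 1/(1 + exp(-2**kappa * x))`` is sampled at ``n``
    evenly spaced points spanning ``[-5, 5]`` (the single point ``x = 0``
    when ``n == 1``) and normalized to sum to 1.  Weights are monotone
    non-decreasing along the list, so mass concentrates at the top of the
    sorted order; ``kappa = -6`` is nearly flat.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not -6.0 <= kappa <= 6.0:
        raise ValueError("kappa must lie in [-6, 6]")
    x = np.linspace(-5.0, 5.0, n) if n > 1 else np.array([0.0])
    f = expit((2.0 ** kappa) * x)
    return f / f.sum()


def select_direction_voxel(state: SimState, cid: int, kappa: float,
                           rng: np.random.Generator,
                           bias_toward: str = "far",
                           free_edges: np.ndarray | None = None,
                           voxels: np.ndarray | None = None) -> np.ndarray:
    """Sample the free-edge voxel through which a new lamellipodium points.

    Free-edge voxels are sorted ascending by cumulative distance to the
    cell's cell-cell border voxels (ties broken lexicographically) and an
    index is drawn from :func:`bias_weights`.  With ``bias_toward="far"``
    (default) the increasing weights put the mass on voxels *farthest*
    from cell-cell contacts, i.e. most opposite the contacts; ``"near"``
    reverses the weight vector (the alternative textual reading).
    With no cell-cell borders at all the draw is uniform.
    """
    if voxels is None:
        voxels = state.cell_voxels(cid)
    if free_edges is None:
        free_edges = free_edge_voxels(state, cid, voxels)
    if len(free_edges) == 0:
        raise ValueError(f"cell {cid} has no free-edge voxels")
    n = len(free_edges)
    border = cell_border_voxels(state, cid, voxels)
    if len(border) == 0:
        return free_edges[rng.integers(n)]
    diffs = free_edges[:, None, :].astype(np.float64) - border[None, :, :]
    cum = np.sqrt((diffs * diffs).sum(axis=2)).sum(axis=1)
    order = np.lexsort((free_edges[:, 2], free_edges[:, 1],
                        free_edges[:, 0], cum))
    weights = bias_weights(n, kappa)
    if bias_toward == "near":
        weights = weights[::-1]
    idx = rng.choice(n, p=weights)
    return free_edges[order[idx]]
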