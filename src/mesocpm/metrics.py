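"""Measurement protocols and the statistics layer.

Unit conventions: lattice lengths in voxels (6 um/voxel), time in MCS
(5 s/MCS), so 1 voxel per MCS = 6 um / 5 s = 4320 um/h.  Speeds are
reported in um/h to match how explant migration is measured at the bench.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import SimConfig
from .state import SimState

#: conversion factor: (voxels per MCS) * VOXEL_MCS_TO_UM_H = um/h
#: at the default 6 um/voxel and 5 s/MCS
VOXEL_MCS_TO_UM_H = 6.0 * 3600.0 / 5.0  # = 4320


def _vox_per_mcs_to_um_h(config: SimConfig) -> float:
    return config.microns_per_voxel * 3600.0 / config.seconds_per_mcs


@dataclass
class TrajectoryRecord:
    """Sampled centroids of tracked cells.

    positions has shape (n_samples, n_cells, 3) in voxel units; mcs is the
    strictly increasing sample times.
    """

    mcs: np.ndarray
    cell_ids: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.mcs = np.asarray(self.mcs, dtype=np.int64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if np.any(np.diff(self.mcs) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.positions.shape[:2] != (len(self.mcs), len(self.cell_ids)):
            raise ValueError("positions shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.mcs)


@dataclass
class AreaRecord:
    """Free-area time series of the ITR central gap (voxel^2)."""

    mcs: np.ndarray
    free_area: np.ndarray

    def __post_init__(self):
        self.mcs = np.asarray(self.mcs, dtype=np.int64)
        self.free_area = np.asarray(self.free_area, dtype=np.float64)
        if np.any(np.diff(self.mcs) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.free_area < 0):
            raise ValueError("free_area must be >= 0")


@dataclass
class ClosureSpeed:
    """Gap side-length shrinkage rate; ``per_edge`` is the advance speed
    of one leading edge (two opposing edges close the side together)."""

    speed_um_h: float
    per_edge_um_h: float


def dmz_migration_speed(trajectory: TrajectoryRecord, config: SimConfig,
                        axis=(1.0, 0.0, 0.0), mode: str = "net") -> float:
    """Mean leading-edge migration speed in um/h.

    Net signed displacement of each tracked cell along the migration axis
    divided by elapsed time, averaged over cells (``mode="net"``, the
    protocol default); ``mode="path"`` instead sums per-sample axial
    distances (a path-length variant).
    """
    if trajectory.n_samples < 2:
        raise ValueError("need at least 2 samples to measure a speed")
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    proj = trajectory.positions @ axis  # (n_samples, n_cells)
    elapsed = float(trajectory.mcs[-1] - trajectory.mcs[0])
    if mode == "net":
        per_cell = (proj[-1] - proj[0]) / elapsed
    elif mode == "path":
        per_cell = np.abs(np.diff(proj, axis=0)).sum(axis=0) / elapsed
    else:
        raise ValueError("mode must be 'net' or 'path'")
    return float(per_cell.mean() * _vox_per_mcs_to_um_h(config))


def itr_closure_speed(area_record: AreaRecord, config: SimConfig) -> ClosureSpeed:
    """Closure speed from the shrinking side length of the central gap.

    side(t) = sqrt(free_area(t)); the speed is |least-squares slope| of
    side vs t over the closing phase (samples with free_area > 0),
    converted to um/h.
    """
    closing = area_record.free_area > 0
    if not closing.any():
        raise ValueError("gap already closed for the whole record")
    t = area_record.mcs[closing].astype(np.float64)
    side = np.sqrt(area_record.free_area[closing])
    if len(t) < 3:
        raise ValueError("need >= 3 closing-phase samples")
    slope = np.polyfit(t, side, 1)[0]
    speed = abs(float(slope)) * _vox_per_mcs_to_um_h(config)
    return ClosureSpeed(speed_um_h=speed, per_edge_um_h=speed / 2.0)


def free_gap_area(state: SimState, gap_bounds) -> int:
    """Open free area of the gap's bounding square, in voxel^2.

    Counts (x, y) columns that contain no cell voxel at any height — the
    cell-free area as seen from above, matching how the open space between
    explants is measured in top-down imaging.  Sub-cellular medium
    pinholes in the covered tissue do not count as free area.
    """
    x_lo, x_hi, y_lo, y_hi = gap_bounds
    block = state.owner[x_lo:x_hi, y_lo:y_hi, 1:]
    return int(np.count_nonzero(~np.any(block > 0, axis=2)))


def substrate_cell_count(state: SimState) -> int:
    """Number of cells with >= 1 voxel face-adjacent to the substrate."""
    return int(len(state.substrate_plane_ids()))


def retraction_distance(trajectory_after_block: TrajectoryRecord,
                        config: SimConfig, axis=(1.0, 0.0, 0.0)) -> float:
    """Mean rearward displacement (um) of tracked leading-row cells from
    block onset (first sample) to the final sample; forward motion after
    the block yields a negative value."""
    traj = trajectory_after_block
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    proj = traj.positions @ axis
    per_cell = proj[0] - proj[-1]  # positive = moved rearward
    return float(per_cell.mean() * config.microns_per_voxel)


# ---------------------------------------------------------------------------
# statistics

def t_test_independent(sample_a, sample_b) -> tuple[float, float]:
    """Unpaired two-tailed Student's t-test (pooled variance)."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 \
            and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def one_way_anova(groups) -> tuple[float, float]:
    """One-way ANOVA F and p across >= 2 groups (common-mean test)."""
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrs) < 2 or any(len(g) < 2 for g in arrs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    within = sum(float(np.var(g, ddof=1)) for g in arrs)
    means = [float(g.mean()) for g in arrs]
    if within == 0 and len(set(means)) == 1:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def sensitivity_slope(levels, mean_outputs) -> float:
    """Least-squares slope of mean output vs fractional parameter change."""
    levels = np.asarray(levels, dtype=np.float64)
    y = np.asarray(mean_outputs, dtype=np.float64)
    if len(levels) < 2:
        raise ValueError("need >= 2 levels")
    return float(np.polyfit(levels, y, 1)[0])
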