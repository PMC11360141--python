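"""Synthetic trajectory and area fixtures.

These generators emit :class:`~mesocpm.metrics.TrajectoryRecord` and
:class:`~mesocpm.metrics.AreaRecord` streams with prescribed drift and
noise, so the measurement layer can be tested independently of the
Cellular-Potts engine (known input motion -> known expected metric).
"""

from __future__ import annotations

import numpy as np

from .metrics import TrajectoryRecord, AreaRecord


def synthetic_trajectory(n_cells: int = 4, n_samples: int = 8,
                         mcs_per_sample: int = 200,
                         drift_per_sample=(1.0, 0.0, 0.0),
                         noise_sd: float = 0.0,
                         start=(10.0, 10.0, 3.0),
                         rng: np.random.Generator | None = None
                         ) -> TrajectoryRecord:
    """Cells drifting ``drift_per_sample`` voxels per sample with optional
    isotropic Gaussian positional noise."""
    rng = rng or np.random.default_rng(0)
    drift = np.asarray(drift_per_sample, dtype=np.float64)
    start = np.asarray(start, dtype=np.float64)
    mcs = np.arange(n_samples, dtype=np.int64) * mcs_per_sample
    base = start[None, None, :] + np.arange(n_samples)[:, None, None] * drift
    base = np.broadcast_to(base, (n_samples, n_cells, 3)).copy()
    # spread cells out laterally so they are distinguishable
    base[:, :, 1] += np.arange(n_cells) * 5.0
    if noise_sd > 0:
        base += rng.normal(0.0, noise_sd, size=base.shape)
    return TrajectoryRecord(mcs=mcs, cell_ids=np.arange(1, n_cells + 1),
                            positions=base)


def synthetic_area_record(initial_side: float = 40.0,
                          side_rate_per_sample: float = 2.0,
                          n_samples: int = 8, mcs_per_sample: int = 200,
                          noise_sd: float = 0.0,
                          rng: np.random.Generator | None = None
                          ) -> AreaRecord:
    """A gap whose side length shrinks linearly (plus optional noise on
    the side length), area = side**2 clipped at 0."""
    rng = rng or np.random.default_rng(0)
    mcs = np.arange(n_samples, dtype=np.int64) * mcs_per_sample
    side = initial_side - side_rate_per_sample * np.arange(n_samples)
    if noise_sd > 0:
        side = side + rng.normal(0.0, noise_sd, size=side.shape)
    side = np.clip(side, 0.0, None)
    return AreaRecord(mcs=mcs, free_area=side ** 2)
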