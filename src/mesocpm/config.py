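"""Simulation configuration.

All model parameters live in :class:`SimConfig`.  The shipped defaults were
calibrated to reproduce the qualitative behaviors of a migrating DMZ
explant (cohesive tissue, persistent forward migration of the leading row
at a speed of order 100 um/h); see ``docs/methods.md`` for the calibration
gates and rationale.  Configs round-trip to plain YAML files whose keys
mirror the field names exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

# Cell-type codes used throughout the lattice machinery.
MEDIUM = 0
SUBSTRATE = 1
LEADER = 2
FOLLOWER = 3

_TYPE_NAMES = {"medium": MEDIUM, "substrate": SUBSTRATE,
               "leader": LEADER, "follower": FOLLOWER}


@dataclass
class ContactEnergy:
    """Symmetric contact-energy table J(tau_a, tau_b) over the four types.

    Only physically meaningful pairs are exposed; leader and follower share
    the same adhesive surface chemistry by default (the leader/follower
    distinction in the model is behavioral, not adhesive).
    """

    cell_medium: float = 8.0
    cell_substrate: float = 4.0
    cell_cell: float = 5.0
    medium_substrate: float = 7.0
    medium_medium: float = 0.0

    def as_matrix(self) -> np.ndarray:
        """Return the full symmetric 4x4 matrix indexed by type code."""
        J = np.zeros((4, 4), dtype=np.float64)
        J[MEDIUM, MEDIUM] = self.medium_medium
        J[MEDIUM, SUBSTRATE] = J[SUBSTRATE, MEDIUM] = self.medium_substrate
        for t in (LEADER, FOLLOWER):
            J[t, MEDIUM] = J[MEDIUM, t] = self.cell_medium
            J[t, SUBSTRATE] = J[SUBSTRATE, t] = self.cell_substrate
            for u in (LEADER, FOLLOWER):
                J[t, u] = self.cell_cell
        return J


@dataclass
class SimConfig:
    """Every tunable model parameter, with calibrated defaults.

    Units: lengths in voxels (1 voxel = ``microns_per_voxel`` um), time in
    Monte-Carlo steps (1 MCS = ``seconds_per_mcs`` s), energies in the
    model's arbitrary effective-energy units.
    """

    # -- effective energy -------------------------------------------------
    contact_energy: ContactEnergy = field(default_factory=ContactEnergy)
    lambda_volume: float = 2.0        # strength of the quadratic volume constraint
    v_target: int = 125               # target cell volume, voxels (5x5x5)
    temperature: float = 24.0         # CPM fluctuation amplitude

    # -- link mechanics ---------------------------------------------------
    lambda_tissue: float = 50.0            # cell-cell spring stiffness
    lambda_lamellipodia: float = 800.0    # lamellipodium constant tension
    lambda_follower_substrate: float = 2.0  # follower-substrate spring stiffness
    link_target_length: float = 5.0       # rest length of cell-cell springs, voxels
    substrate_link_target_length: float = 3.0  # rest length of follower-substrate springs

    # -- Poisson link turnover (rates per timestep) -----------------------
    zeta_lamellipodia: float = 0.25
    zeta_substrate: float = 0.25
    zeta_tissue: float = 0.0          # 0 disables intercalation (baseline model)

    # -- lamellipodium geometry and cohesotaxis ---------------------------
    chi_lamellipodia: float = 12.0    # anchor distance beyond the selected voxel, voxels
    kappa: float = 6.0                # cohesotaxis bias in [-6, 6]
    bias_toward: str = "far"          # "far": protrude away from cell-cell contacts
    lamellipodium_reach_tolerance: float = 1.0  # in-plane satisfied distance, voxels

    # -- intercalation ----------------------------------------------------
    max_reformed_neighbors: int = 4

    # -- geometry / protocol ----------------------------------------------
    leader_rows: str = "bottom"       # "bottom": 8-cell bottom leading row
    itr_gap: int = 40                 # ITR central free square side, voxels
    n_mcs: int = 1440                 # default run length (2 h at 5 s/MCS)
    mcs_per_sample: int = 200         # centroid/area sampling cadence
    seconds_per_mcs: float = 5.0
    microns_per_voxel: float = 6.0    # 30 um cells / 5 voxels

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def contact_matrix(self) -> np.ndarray:
        """Cached 4x4 contact-energy matrix for the inner loop."""
        J = getattr(self, "_J_cache", None)
        if J is None:
            J = self.contact_energy.as_matrix()
            object.__setattr__(self, "_J_cache", J)
        return J

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.v_target <= 0:
            raise ValueError("v_target must be > 0")
        for name in ("zeta_lamellipodia", "zeta_substrate", "zeta_tissue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -6.0 <= self.kappa <= 6.0:
            raise ValueError("kappa must lie in [-6, 6]")
        if self.bias_toward not in ("far", "near"):
            raise ValueError("bias_toward must be 'far' or 'near'")
        if self.leader_rows not in ("bottom", "full_face"):
            raise ValueError("leader_rows must be 'bottom' or 'full_face'")

    def replace(self, **kw) -> "SimConfig":
        """Return a copy with the given fields overridden."""
        if "contact_energy" in kw and isinstance(kw["contact_energy"], dict):
            kw["contact_energy"] = ContactEnergy(**kw["contact_energy"])
        return dataclasses.replace(self, **kw)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "contact_energy" in d and isinstance(d["contact_energy"], dict):
            d["contact_energy"] = ContactEnergy(**d["contact_energy"])
        return cls(**d)


def load_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file with keys mirroring field names."""
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_config(**overrides) -> SimConfig:
    """The shipped calibrated default parameterization."""
    return SimConfig().replace(**overrides) if overrides else SimConfig()
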