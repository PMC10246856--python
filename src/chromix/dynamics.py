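"""Langevin dynamics driver: NVT integration, neighbor lists, trajectories.

The integrator is velocity Verlet with an exact Ornstein-Uhlenbeck
thermostat sweep (BAOAB splitting), the standard analogue of a LAMMPS
``fix langevin`` run.  With the thermostat disabled it reduces exactly to
velocity Verlet, which is used for energy-conservation checks.  An
overdamped Brownian-dynamics mode is available behind a flag.

Time bookkeeping: the internal step is ``dt`` in simulation units with bead
mass m = 1 and friction time ``damping``; frame times are reported in
Brownian times tau (the time a free bead needs to diffuse sigma^2), using
tau = sigma^2 / D with D = k_B T * damping / m.  At the defaults
(temperature 1, damping 1) one simulation time unit is one tau.
"""

from __future__ import annotations

import gzip

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from ._kernels import PAIR_BY_TYPE, PAIR_INTRA_INTER
from .forcefield import ForceField, effective_type_index
from .model_core import LAMIN, PolymerSystem

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "IntegrationBlowUpError",
    "build_neighbor_list",
    "langevin_step",
    "run_simulation",
]

_TYPE_NAMES = {0: "EU", 1: "HET", 2: "LAMIN"}
_TYPE_CODES = {v: k for k, v in _TYPE_NAMES.items()}


class IntegrationBlowUpError(RuntimeError):
    """Raised when a coordinate becomes non-finite; carries the step index
    and any trajectory frames dumped before the failure."""

    def __init__(self, step, trajectory=None):
        super().__init__(f"integration blew up at step {step}")
        self.step = step
        self.trajectory = trajectory


@dataclass
class SimulationConfig:
    """Integration parameters (reduced units)."""

    n_steps: int = 10000
    dump_every: int = 100
    dt: float = 0.01          # integration step
    damping: float = 1.0      # friction time; gamma = 1/damping
    temperature: float = 1.0  # k_BT
    seed: int = 0
    neighbor_skin: float = 0.6
    thermostat: bool = True
    overdamped: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps % self.dump_every != 0:
            raise ValueError("dump_every must divide n_steps")

    @property
    def time_scale_tau(self) -> float:
        """Brownian times per simulation time unit (= D in reduced units)."""
        d = self.temperature * self.damping
        return d if d > 0 else 1.0

    def to_dict(self):
        return asdict(self)


@dataclass
class Trajectory:
    """Frame stack with times in tau and provenance metadata."""

    frames: np.ndarray          # (F, N, 3)
    times: np.ndarray           # (F,) in tau
    chain_id: np.ndarray
    bead_type: np.ndarray
    lad_flag: np.ndarray
    confinement_radius: float = math.inf
    metadata: dict = field(default_factory=dict)
    energies: np.ndarray = None      # (F, 6): spring/bend/lj/wall/indenter/kinetic
    kinetic_temperature: np.ndarray = None

    def __post_init__(self):
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must increase monotonically")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def chain_offsets(self) -> np.ndarray:
        mobile_chains = self.chain_id[self.bead_type != LAMIN]
        counts = np.bincount(mobile_chains)
        return np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    # -- extended-XYZ ------------------------------------------------------

    def write_xyz(self, path):
        """Extended-XYZ, one block per frame; gzip when path ends in .gz."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for f in range(self.n_frames):
                fh.write(f"{self.n_beads}\n")
                fh.write(
                    f"time={self.times[f]:.6g} rc={self.confinement_radius:.6g} "
                    "Properties=species:S:1:pos:R:3:chain:I:1:lad:I:1\n"
                )
                pos = self.frames[f]
                for i in range(self.n_beads):
                    t = _TYPE_NAMES.get(int(self.bead_type[i]), "EU")
                    fh.write(
                        f"{t} {pos[i, 0]:.6f} {pos[i, 1]:.6f} {pos[i, 2]:.6f} "
                        f"{int(self.chain_id[i])} {int(self.lad_flag[i])}\n"
                    )

    @classmethod
    def read_xyz(cls, path):
        opener = gzip.open if str(path).endswith(".gz") else open
        frames, times = [], []
        chain_id = bead_type = lad = None
        rc = math.inf
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header.strip():
                    break
                n = int(header)
                comment = fh.readline()
                fields = dict(
                    kv.split("=", 1) for kv in comment.split() if "=" in kv
                )
                times.append(float(fields.get("time", len(times))))
                rc = float(fields.get("rc", math.inf))
                pos = np.empty((n, 3))
                cid = np.empty(n, np.int32)
                bt = np.empty(n, np.int8)
                lf = np.zeros(n, bool)
                for i in range(n):
                    parts = fh.readline().split()
                    bt[i] = _TYPE_CODES.get(parts[0], 0)
                    pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                    cid[i] = int(parts[4])
                    lf[i] = bool(int(parts[5]))
                frames.append(pos)
                chain_id, bead_type, lad = cid, bt, lf
        return cls(
            frames=np.array(frames),
            times=np.array(times),
            chain_id=chain_id,
            bead_type=bead_type,
            lad_flag=lad,
            confinement_radius=rc,
        )


def build_neighbor_list(positions, max_cutoff, skin, chain_id=None, mobile=None):
    """Candidate pair list containing every pair within max_cutoff + skin.

    Symmetric (each unordered pair once), bonded (consecutive same-chain)
    pairs excluded.  Backed by a linked-cell grid; identical in content to a
    brute-force O(N^2) scan.
    """
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    n = len(pos)
    if chain_id is None:
        chain_id = np.zeros(n, np.int32)
    if mobile is None:
        mobile = np.ones(n, bool)
    return _kernels.cell_list_pairs(
        pos, np.asarray(chain_id, np.int32), np.asarray(mobile, bool),
        float(max_cutoff) + float(skin),
    )


def _kernel_args(system: PolymerSystem, ff: ForceField, pair_override=None):
    type_idx = effective_type_index(system.bead_type, system.lad_flag)
    if pair_override is None:
        mode, ei, ci, ee, ce = PAIR_BY_TYPE, 0.0, 0.0, 0.0, 0.0
        max_cut = ff.max_cutoff
    else:
        ei, ci, ee, ce = pair_override
        mode = PAIR_INTRA_INTER
        max_cut = max(ci, ce)
    has_pairs = max_cut > 0
    rc = system.confinement_radius if math.isfinite(system.confinement_radius) else np.inf
    return type_idx, mode, ei, ci, ee, ce, has_pairs, max_cut, rc


def run_simulation(system, forcefield, config, indenter=None, pair_override=None,
                   start_time_tau=0.0, step_offset=0, force_cap=None):
    """Integrate a system and return the sampled trajectory.

    Parameters
    ----------
    indenter : (K_indent, R_indent) or None
        Spherical indenter active during the run (compression protocol).
    pair_override : (eps_intra, cut_intra, eps_inter, cut_inter) or None
        When given, pair interactions ignore bead types and depend only on
        whether the two beads share a chain (compression protocol).
    step_offset : int
        Global step index of the first step; feeds the counter RNG so
        consecutive segments of a run are statistically independent.
    force_cap : float or None
        Cap on the magnitude of any single pair force.  The default caps
        only the deep-overlap catastrophe (1e4); a small value (~50) acts
        as a soft push-off for freshly packed, overlapping start states.

    The system is advanced in place; energies and the realized kinetic
    temperature are logged at every dump.
    """
    cfg = config
    n_frames = cfg.n_steps // cfg.dump_every
    frames = np.empty((n_frames, system.n_beads, 3))
    frame_steps = np.zeros(n_frames, np.int64)
    e_log = np.zeros((n_frames, 6))
    t_kin = np.zeros(n_frames)
    type_idx, mode, ei, ci, ee, ce, has_pairs, max_cut, rc = _kernel_args(
        system, forcefield, pair_override
    )
    K_ind, R_ind = (0.0, 0.0) if indenter is None else indenter
    gamma = 1.0 / cfg.damping
    f_cap = _kernels.FORCE_CAP if force_cap is None else float(force_cap)
    common = (
        system.bonds, system.angle_triples, type_idx,
        np.asarray(system.chain_id, np.int32), np.asarray(system.mobile_mask, bool),
        forcefield.k_spring, forcefield.k_bend,
        forcefield.eps_matrix, forcefield.cutoff_matrix, forcefield.lj_shifted,
        mode, ei, ci, ee, ce,
        rc, forcefield.wall_strength, float(K_ind), float(R_ind), f_cap,
    )
    if cfg.overdamped:
        mobility = cfg.damping  # 1/(m*gamma)
        err_step, ncap = _kernels.run_bd(
            system.positions, *common,
            cfg.dt, mobility, cfg.temperature, has_pairs, max_cut,
            cfg.neighbor_skin, cfg.n_steps, cfg.dump_every,
            np.uint64(cfg.seed), np.uint64(step_offset),
            frames, frame_steps, e_log, t_kin,
        )
    else:
        err_step, ncap = _kernels.run_nvt(
            system.positions, system.velocities, *common,
            cfg.dt, gamma, cfg.temperature, cfg.thermostat, has_pairs, max_cut,
            cfg.neighbor_skin, cfg.n_steps, cfg.dump_every,
            np.uint64(cfg.seed), np.uint64(step_offset),
            frames, frame_steps, e_log, t_kin,
        )
    n_ok = int(np.sum(frame_steps > 0))
    times = start_time_tau + (frame_steps[:n_ok] - step_offset) * cfg.dt * cfg.time_scale_tau
    traj = Trajectory(
        frames=frames[:n_ok],
        times=times,
        chain_id=system.chain_id.copy(),
        bead_type=system.bead_type.copy(),
        lad_flag=system.lad_flag.copy(),
        confinement_radius=system.confinement_radius,
        metadata={
            "config": cfg.to_dict(),
            "seed": cfg.seed,
            "capped_forces": int(ncap),
            "indenter": None if indenter is None else list(indenter),
        },
        energies=e_log[:n_ok],
        kinetic_temperature=t_kin[:n_ok],
    )
    if err_step >= 0:
        raise IntegrationBlowUpError(err_step, trajectory=traj)
    return traj


def langevin_step(system, forcefield, config, step_index=0):
    """Advance the system by a single Langevin step (in place).

    The noise depends only on (config.seed, step_index, bead, axis), so
    stepping a system twice from identical states and indices is bitwise
    reproducible.
    """
    one = SimulationConfig(
        n_steps=1, dump_every=1, dt=config.dt, damping=config.damping,
        temperature=config.temperature, seed=config.seed,
        neighbor_skin=config.neighbor_skin, thermostat=config.thermostat,
        overdamped=config.overdamped,
    )
    run_simulation(system, forcefield, one, step_offset=step_index)
    return system
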