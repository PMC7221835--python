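"""Langevin dynamics engine: forces, BAOAB propagation, checkpointing.

The integrator is the BAOAB splitting of Langevin dynamics, which reduces
exactly to velocity Verlet when temperature and friction are zero.  The
noise stream is owned by a ``numpy.random.Generator`` carried on the
simulation state, so trajectories are reproducible bit-for-bit from a
seed and checkpoints can resume the identical stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .toy_receptor import ParticleSystem
from .units import KB, KCAL_TO_AKMA

CHECKPOINT_FORMAT = "ligandpath-checkpoint-1"


class SimulationBlowUpError(RuntimeError):
    """Dynamics produced non-finite or absurd forces; try a smaller dt."""


class CheckpointError(RuntimeError):
    """A checkpoint file is missing fields, corrupted, or unversioned."""


# --------------------------------------------------------------------------
# energies / forces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyTerms:
    """Potential-energy decomposition, kcal/mol.

    ``e_total`` is always formed as e_bond + e_lj + e_coulomb + e_restraint
    in that fixed order, so the decomposition identity is exact.
    """

    e_bond: float
    e_lj: float
    e_coulomb: float
    e_restraint: float

    @property
    def e_total(self) -> float:
        return self.e_bond + self.e_lj + self.e_coulomb + self.e_restraint


def _exclusion_matrix(system: ParticleSystem) -> np.ndarray:
    """Nonbonded exclusions: bonded pairs, and restrained–restrained pairs.

    The restrained scaffold is held near its build geometry by tethers;
    its deliberately overlapping beads (rod-like pillars, bead sheets)
    would otherwise contribute enormous constant LJ terms, so
    scaffold-internal nonbonded interactions are excluded — only pairs
    involving at least one free particle interact.
    """
    n = system.n_particles
    excl = np.zeros((n, n), dtype=np.uint8)
    r = system.restrained
    excl[np.ix_(r, r)] = 1
    for i, j in system.bonds:
        excl[i, j] = 1
        excl[j, i] = 1
    return excl


def compute_forces(system: ParticleSystem, positions: Optional[np.ndarray] = None
                   ) -> Tuple[np.ndarray, EnergyTerms]:
    """Forces (kcal/mol/Å, shape N×3) and energy terms at given positions.

    Forces are the exact negative gradient of the reported energy; bonded
    pairs are excluded from the nonbonded sum.
    """
    pos = system.positions if positions is None else np.asarray(positions, float)
    if pos.shape != (system.n_particles, 3):
        raise ValueError(f"positions must have shape ({system.n_particles}, 3)")
    bad = ~np.isfinite(pos).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite coordinates for particle {int(np.nonzero(bad)[0][0])}")
    forces = np.empty_like(pos)
    e_bond, e_lj, e_coul, e_restr = _kernels.forces_energies(
        np.ascontiguousarray(pos), system.charges, system.lj_epsilon,
        system.lj_sigma, _exclusion_matrix(system), system.bonds,
        system.bond_k, system.bond_r0, system.restrained,
        system.reference_positions, system.restraint_k,
        system.container_center, system.container_radius, system.container_k,
        system.cutoff, system.switch_on, forces)
    return forces, EnergyTerms(e_bond, e_lj, e_coul, e_restr)


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kcal/mol from Å/ps velocities and amu masses."""
    return float(0.5 * np.sum(masses[:, None] * velocities ** 2) / KCAL_TO_AKMA)


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Thermal velocities, Å/ps, at the given temperature."""
    sigma = np.sqrt(KB * temperature * KCAL_TO_AKMA / masses)
    return sigma[:, None] * rng.standard_normal((masses.shape[0], 3))


# --------------------------------------------------------------------------
# simulation state
# --------------------------------------------------------------------------


@dataclass
class SimState:
    """Instantaneous dynamical state, including the noise stream."""

    positions: np.ndarray      # (N, 3) Å
    velocities: np.ndarray     # (N, 3) Å/ps
    time: float = 0.0          # ps
    step: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))
    rng_label: str = "pcg64:0"

    def copy(self) -> "SimState":
        rng = np.random.Generator(np.random.PCG64())
        rng.bit_generator.state = self.rng.bit_generator.state
        return SimState(self.positions.copy(), self.velocities.copy(),
                        self.time, self.step, rng, self.rng_label)


def initial_state(system: ParticleSystem, temperature: float = 0.0,
                  seed: int = 0) -> SimState:
    """Fresh state: build positions, thermal (or zero) velocities."""
    rng = np.random.Generator(np.random.PCG64(seed))
    n = system.n_particles
    if temperature > 0.0:
        vel = maxwell_boltzmann_velocities(system.masses, temperature, rng)
    else:
        vel = np.zeros((n, 3))
    return SimState(system.positions.copy(), vel, 0.0, 0, rng, f"pcg64:{seed}")


# --------------------------------------------------------------------------
# propagation
# --------------------------------------------------------------------------

_EMPTY_IDX = np.empty(0, dtype=np.int64)
_ZERO3 = np.zeros(3)


@dataclass
class Trajectory:
    """Recorded frames of one run: times (F,) ps and positions (F, N, 3) Å."""

    times: np.ndarray
    frames: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _propagate(system: ParticleSystem, state: SimState, n_steps: int, dt: float,
               temperature: float, friction: float,
               pull_idx: np.ndarray = _EMPTY_IDX, k_spring: float = 0.0,
               anchor0: np.ndarray = _ZERO3, anchor_vel: np.ndarray = _ZERO3,
               record_every: int = 0, traj_every: int = 0, chunk: int = 20000):
    """Shared inner driver; mutates nothing, returns (state, records, traj).

    ``records`` is None unless ``record_every`` > 0, else a dict of arrays
    (t, anchor, com, force in kcal/mol/Å).  Noise is drawn from the state's
    generator in fixed-size requests so the stream is independent of the
    chunking.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if friction < 0:
        raise ValueError("friction must be >= 0")
    new = state.copy()
    pos = np.ascontiguousarray(new.positions)
    vel = np.ascontiguousarray(new.velocities)
    kT = KB * max(temperature, 0.0)
    excl = _exclusion_matrix(system)

    n = system.n_particles
    n_rec_total = (n_steps // record_every + 1) if record_every > 0 else 0
    n_traj_total = (n_steps // traj_every + 1) if traj_every > 0 else 0
    rec_t = np.empty(max(n_rec_total, 1))
    rec_anchor = np.zeros((max(n_rec_total, 1), 3))
    rec_com = np.zeros((max(n_rec_total, 1), 3))
    rec_force = np.zeros((max(n_rec_total, 1), 3))
    traj_t = np.empty(max(n_traj_total, 1))
    traj_frames = np.empty((max(n_traj_total, 1), n, 3))

    # The kernel is called once over all steps when the noise array fits;
    # otherwise we loop in chunks, re-aligning the local recording phase.
    done = 0
    rec_filled = 0
    traj_filled = 0
    while True:
        todo = min(chunk, n_steps - done)
        if friction > 0.0 and temperature > 0.0:
            noise = new.rng.standard_normal((todo, n, 3))
        else:
            noise = np.zeros((todo, n, 3))
        # local record buffers for this chunk
        lr = (todo // record_every + 1) if record_every > 0 else 0
        lt = (todo // traj_every + 1) if traj_every > 0 else 0
        c_rec_t = np.empty(max(lr, 1))
        c_rec_anchor = np.zeros((max(lr, 1), 3))
        c_rec_com = np.zeros((max(lr, 1), 3))
        c_rec_force = np.zeros((max(lr, 1), 3))
        c_traj_t = np.empty(max(lt, 1))
        c_traj_frames = np.empty((max(lt, 1), n, 3))
        a0 = anchor0 + anchor_vel * (done * dt)
        status, n_rec, n_traj = _kernels.run_baoab(
            pos, vel, system.masses, system.charges, system.lj_epsilon,
            system.lj_sigma, excl, system.bonds, system.bond_k, system.bond_r0,
            system.restrained, system.reference_positions, system.restraint_k,
            system.container_center, system.container_radius, system.container_k,
            system.cutoff, system.switch_on, todo, dt, friction, kT, noise,
            pull_idx, k_spring, a0, np.asarray(anchor_vel, float),
            record_every, c_rec_t, c_rec_anchor, c_rec_com, c_rec_force,
            traj_every, c_traj_t, c_traj_frames)
        if status == _kernels.STATUS_BLOWUP:
            raise SimulationBlowUpError(
                f"dynamics blew up near step {new.step + done} "
                f"(t ≈ {new.time + done * dt:.3f} ps); try a smaller dt")
        start = 0 if done == 0 else 1  # chunk records its own step 0 again
        if record_every > 0:
            for k in range(start, n_rec):
                rec_t[rec_filled] = c_rec_t[k] + done * dt
                rec_anchor[rec_filled] = c_rec_anchor[k]
                rec_com[rec_filled] = c_rec_com[k]
                rec_force[rec_filled] = c_rec_force[k]
                rec_filled += 1
        if traj_every > 0:
            for k in range(start, n_traj):
                traj_t[traj_filled] = c_traj_t[k] + done * dt
                traj_frames[traj_filled] = c_traj_frames[k]
                traj_filled += 1
        done += todo
        if done >= n_steps:
            break
        if record_every > 0 and done % record_every != 0:
            raise ValueError("chunk size must be a multiple of record_every")
        if traj_every > 0 and done % traj_every != 0:
            raise ValueError("chunk size must be a multiple of traj_every")

    new.positions = pos
    new.velocities = vel
    new.time = state.time + n_steps * dt
    new.step = state.step + n_steps

    records = None
    if record_every > 0:
        records = {
            "t": rec_t[:rec_filled].copy(),
            "anchor": rec_anchor[:rec_filled].copy(),
            "com": rec_com[:rec_filled].copy(),
            "force": rec_force[:rec_filled].copy(),
        }
    traj = None
    if traj_every > 0:
        traj = Trajectory(traj_t[:traj_filled].copy(), traj_frames[:traj_filled].copy())
    return new, records, traj


def step_langevin(system: ParticleSystem, state: SimState, n_steps: int,
                  dt: float, temperature: float, friction: float,
                  seed: Optional[int] = None) -> SimState:
    """Propagate ``n_steps`` of BAOAB Langevin dynamics; returns a new state.

    With ``seed`` given, the state's noise stream is replaced by a fresh
    PCG64 stream (the original continuation then diverges); with ``seed``
    None the state's own stream continues, so restoring a checkpoint and
    re-propagating reproduces the original trajectory exactly.
    """
    work = state.copy()
    if seed is not None:
        work.rng = np.random.Generator(np.random.PCG64(seed))
        work.rng_label = f"pcg64:{seed}"
    new, _, _ = _propagate(system, work, n_steps, dt, temperature, friction)
    return new


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------


@dataclass
class Checkpoint:
    """Snapshot of a :class:`SimState` plus a monotone checkpoint index."""

    state: SimState
    index: int = 0


def save_checkpoint(state: SimState, index: int = 0) -> Checkpoint:
    return Checkpoint(state.copy(), index)


def restore_checkpoint(cp: Checkpoint) -> SimState:
    return cp.state.copy()


def write_checkpoint(cp: Checkpoint, path) -> None:
    """Serialize a checkpoint as versioned JSON (bit-exact round trip)."""
    rng_state = cp.state.rng.bit_generator.state
    payload = {
        "format": CHECKPOINT_FORMAT,
        "index": cp.index,
        "time": cp.state.time,
        "step": cp.state.step,
        "rng_label": cp.state.rng_label,
        "rng_state": {
            "bit_generator": rng_state["bit_generator"],
            "state": {k: int(v) for k, v in rng_state["state"].items()},
            "has_uint32": int(rng_state["has_uint32"]),
            "uinteger": int(rng_state["uinteger"]),
        },
        "positions": cp.state.positions.tolist(),
        "velocities": cp.state.velocities.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_checkpoint(path) -> Checkpoint:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"cannot load checkpoint {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != CHECKPOINT_FORMAT:
        raise CheckpointError(
            f"{path} is not a {CHECKPOINT_FORMAT} file "
            f"(format tag: {payload.get('format') if isinstance(payload, dict) else None!r})")
    required = {"index", "time", "step", "rng_label", "rng_state",
                "positions", "velocities"}
    missing = required - payload.keys()
    if missing:
        raise CheckpointError(f"checkpoint {path} missing fields: {sorted(missing)}")
    rng = np.random.Generator(np.random.PCG64())
    rs = payload["rng_state"]
    rng.bit_generator.state = {
        "bit_generator": rs["bit_generator"],
        "state": {k: int(v) for k, v in rs["state"].items()},
        "has_uint32": int(rs["has_uint32"]),
        "uinteger": int(rs["uinteger"]),
    }
    state = SimState(
        positions=np.array(payload["positions"], dtype=np.float64),
        velocities=np.array(payload["velocities"], dtype=np.float64),
        time=float(payload["time"]),
        step=int(payload["step"]),
        rng=rng,
        rng_label=payload["rng_label"],
    )
    return Checkpoint(state, int(payload["index"]))
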