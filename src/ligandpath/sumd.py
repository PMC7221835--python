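"""Distance-supervised molecular dynamics (SuMD).

Unbiased Langevin dynamics is run in short slices while the distance
between the ligand COM and the binding-site center is monitored.  A slice
is accepted if it brings the ligand closer (by at least a tolerance ε, or
below the best distance seen so far); otherwise the simulation is
restarted from the pre-slice checkpoint with freshly resampled
Maxwell–Boltzmann velocities under a new seed.  Seeds are never reused at
a checkpoint (tabu), and no biasing force is ever applied — an accepted
slice is an ordinary unbiased trajectory segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .dynamics import (SimState, Trajectory, _propagate,
                       maxwell_boltzmann_velocities, restore_checkpoint,
                       save_checkpoint)
from .toy_receptor import ParticleSystem


@dataclass(frozen=True)
class SuMDConfig:
    """Supervision parameters plus the dynamics settings of each slice."""

    site_center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    arrival_radius: float = 4.0        # Å: supervision target reached
    slice_length: int = 100            # steps per supervised slice
    epsilon: float = 0.1               # Å: minimum required approach
    max_consecutive_rejects: int = 50
    max_total_steps: int = 300_000
    base_seed: int = 0                 # attempt k uses seed base_seed + k
    dt: float = 0.01                   # ps
    temperature: float = 300.0         # K
    friction: float = 1.0              # 1/ps
    record_every: int = 10             # steps between recorded frames

    def __post_init__(self):
        if self.slice_length < 1:
            raise ValueError("slice_length must be >= 1")
        if self.arrival_radius <= 0:
            raise ValueError("arrival_radius must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.slice_length % self.record_every != 0:
            raise ValueError("slice_length must be a multiple of record_every")


@dataclass
class SuMDResult:
    """Outcome of one supervised run."""

    trajectory: Trajectory             # concatenated accepted frames
    distances: np.ndarray              # ligand-site distance per frame, Å
    attempts: pd.DataFrame             # slice, seed, accepted, d_start, d_end
    termination: str                   # arrived | reject_cap | step_budget
    restart_count: int
    total_steps: int                   # every attempted slice counts
    final_state: SimState
    system: ParticleSystem
    config: SuMDConfig


def ligand_site_distance(system: ParticleSystem, positions: np.ndarray,
                         site_center) -> float:
    """|COM_ligand − site_center| in Å."""
    lig = system.ligand_indices
    com = np.average(positions[lig], axis=0, weights=system.masses[lig])
    return float(np.linalg.norm(com - np.asarray(site_center, float)))


def run_slice(system: ParticleSystem, state: SimState, config: SuMDConfig,
              seed: int) -> Tuple[SimState, Trajectory]:
    """One unbiased slice: resample velocities under ``seed``, propagate.

    This is exactly what the supervisor runs per attempt; it applies no
    biasing force, so replaying an accepted slice with its logged seed
    reproduces the accepted segment identically.
    """
    work = state.copy()
    rng = np.random.Generator(np.random.PCG64(seed))
    work.velocities = maxwell_boltzmann_velocities(system.masses,
                                                   config.temperature, rng)
    work.rng = rng
    work.rng_label = f"pcg64:{seed}"
    new, _, traj = _propagate(system, work, config.slice_length, config.dt,
                              config.temperature, config.friction,
                              traj_every=config.record_every)
    return new, traj


def supervise(system: ParticleSystem, state: SimState,
              config: SuMDConfig) -> SuMDResult:
    """Run the supervision loop until arrival, reject cap, or step budget.

    Acceptance rule per slice: d_end < d_start − ε, or d_end below the
    best distance seen so far.  On rejection the pre-slice checkpoint is
    restored and the next attempt uses the next seed of the policy, so no
    seed is ever tried twice at the same checkpoint.
    """
    d0 = ligand_site_distance(system, state.positions, config.site_center)
    if d0 <= config.arrival_radius:
        raise ValueError(
            f"ligand already within arrival radius ({d0:.2f} ≤ "
            f"{config.arrival_radius:.2f} Å) — nothing to supervise")

    frames: List[np.ndarray] = [state.positions.copy()]
    times: List[float] = [0.0]
    dists: List[float] = [d0]
    log: List[dict] = []

    current = state
    d_start = d0
    best = d0
    attempt = 0
    consecutive = 0
    restarts = 0
    total_steps = 0
    accepted_slices = 0
    termination = "step_budget"
    cp_index = 0

    while total_steps + config.slice_length <= config.max_total_steps:
        cp = save_checkpoint(current, index=cp_index)
        seed = config.base_seed + attempt
        attempt += 1
        end_state, traj = run_slice(system, restore_checkpoint(cp), config, seed)
        total_steps += config.slice_length
        d_end = ligand_site_distance(system, end_state.positions,
                                     config.site_center)
        accepted = d_end < d_start - config.epsilon or d_end < best
        log.append({"slice": accepted_slices, "seed": seed,
                    "accepted": accepted, "d_start": d_start, "d_end": d_end})
        if accepted:
            t_offset = times[-1]
            frames.extend(traj.frames[1:])  # frame 0 duplicates checkpoint
            times.extend(t_offset + traj.times[1:])
            for frame in traj.frames[1:]:
                dists.append(ligand_site_distance(system, frame,
                                                  config.site_center))
            current = end_state
            d_start = d_end
            best = min(best, d_end)
            consecutive = 0
            accepted_slices += 1
            cp_index += 1
            if d_end <= config.arrival_radius:
                termination = "arrived"
                break
        else:
            current = restore_checkpoint(cp)
            consecutive += 1
            restarts += 1
            if consecutive >= config.max_consecutive_rejects:
                termination = "reject_cap"
                break

    trajectory = Trajectory(np.asarray(times), np.asarray(frames))
    return SuMDResult(trajectory=trajectory, distances=np.asarray(dists),
                      attempts=pd.DataFrame(
                          log, columns=["slice", "seed", "accepted",
                                        "d_start", "d_end"]),
                      termination=termination, restart_count=restarts,
                      total_steps=total_steps, final_state=current,
                      system=system, config=config)


def plain_md_arrival(system: ParticleSystem, state: SimState,
                     config: SuMDConfig, seed: Optional[int] = None) -> int:
    """Steps until plain (unsupervised) dynamics first reaches the site.

    The counterpart experiment to :func:`supervise`: identical dynamics,
    identical arrival test at the same slice granularity, but rejected
    progress is never rolled back because nothing is rejected.  Returns
    the step count at arrival, or ``config.max_total_steps`` if the
    budget runs out first (a censored observation).
    """
    work = state.copy()
    if seed is not None:
        work.rng = np.random.Generator(np.random.PCG64(seed))
        work.velocities = maxwell_boltzmann_velocities(
            system.masses, config.temperature, work.rng)
        work.rng_label = f"pcg64:{seed}"
    steps = 0
    while steps < config.max_total_steps:
        work, _, _ = _propagate(system, work, config.slice_length, config.dt,
                                config.temperature, config.friction)
        steps += config.slice_length
        d = ligand_site_distance(system, work.positions, config.site_center)
        if d <= config.arrival_radius:
            return steps
    return config.max_total_steps


def distance_series(result: SuMDResult) -> pd.DataFrame:
    """(time, d) table over the accepted frames of a supervised run."""
    if result.trajectory.n_frames == 0:
        raise ValueError("empty SuMD result")
    return pd.DataFrame({"t_ps": result.trajectory.times,
                         "d_A": result.distances})


def switch_to_plain_md(result: SuMDResult, extra_steps: int,
                       seed: Optional[int] = None) -> Trajectory:
    """Continue from the final accepted state without supervision.

    Returns the accepted trajectory extended by ``extra_steps`` of plain
    Langevin dynamics (recorded at the supervisor's frame stride); with
    ``extra_steps`` = 0 the trajectory is returned unchanged.
    """
    if extra_steps < 0:
        raise ValueError("extra_steps must be >= 0")
    cfg = result.config
    if extra_steps == 0:
        return Trajectory(result.trajectory.times.copy(),
                          result.trajectory.frames.copy())
    work = result.final_state.copy()
    if seed is not None:
        work.rng = np.random.Generator(np.random.PCG64(seed))
        work.rng_label = f"pcg64:{seed}"
    _, _, traj = _propagate(result.system, work, extra_steps, cfg.dt,
                            cfg.temperature, cfg.friction,
                            traj_every=cfg.record_every)
    t0 = result.trajectory.times[-1]
    times = np.concatenate([result.trajectory.times, t0 + traj.times[1:]])
    frames = np.concatenate([result.trajectory.frames, traj.frames[1:]])
    return Trajectory(times, frames)
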