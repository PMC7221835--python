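"""Constant-velocity steered pulling with a virtual COM spring.

A harmonic spring (stiffness ``k``, pN/Å) connects the center of mass of
a selected ligand-bead subset to a virtual anchor that moves at constant
speed ``v`` along a chosen exit direction.  The spring force is recorded
as a full 3-vector over time; work analysis integrates it against the
pulled-COM displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .dynamics import SimState, Trajectory, _propagate
from .toy_receptor import ParticleSystem
from .units import (KCAL_PER_MOL_ANG_TO_PN, M_PER_S_TO_ANG_PER_PS,
                    PN_TO_KCAL_PER_MOL_ANG)


@dataclass(frozen=True)
class DirectionSpec:
    """A labelled pulling direction (unit vector, normalized on creation)."""

    label: str
    unit_vector: Tuple[float, float, float]

    def __post_init__(self):
        v = np.asarray(self.unit_vector, dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("direction vector must be non-zero")
        object.__setattr__(self, "unit_vector", tuple(v / norm))

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.unit_vector)


def standard_directions(layout) -> list[DirectionSpec]:
    """The five exit directions of the pulling comparison for a 7-helix ring."""
    return [DirectionSpec(label, tuple(vec))
            for label, vec in layout.exit_direction_vectors().items()]


@dataclass(frozen=True)
class PullSchedule:
    """Spring and anchor schedule for one pull.

    ``k`` in pN/Å and ``v`` in m/s follow the conventions of steered-MD
    reports; ``v`` is converted internally with 1 m/s = 0.01 Å/ps exactly.
    The reference all-atom protocol (k = 70 pN/Å, v = 0.3 m/s, 15 ns) is
    available as :func:`reference_schedule`; the toy default trades speed
    for desk-scale runtimes (see the methods note).
    """

    k: float = 70.0             # pN/Å
    v: float = 15.0             # m/s
    duration: float = 120.0     # ps
    record_every: int = 10      # steps between recorded samples

    def __post_init__(self):
        if self.k <= 0 or self.v < 0 or self.duration <= 0:
            raise ValueError("k and duration must be > 0 and v >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @property
    def v_ang_per_ps(self) -> float:
        return self.v * M_PER_S_TO_ANG_PER_PS

    @property
    def k_kcal(self) -> float:
        return self.k * PN_TO_KCAL_PER_MOL_ANG


def reference_schedule(duration: float = 15000.0) -> PullSchedule:
    """The all-atom protocol: k = 70 pN/Å, v = 0.3 m/s, 15 ns."""
    return PullSchedule(k=70.0, v=0.3, duration=duration)


@dataclass
class ForceRecord:
    """Time series of one pull: anchor, pulled COM and spring force.

    Times are ps, positions Å, forces pN (full 3-vectors).  The anchor
    advances exactly as anchor(t) = anchor(0) + v·t·û.
    """

    time: np.ndarray            # (T,)
    anchor: np.ndarray          # (T, 3)
    pulled_com: np.ndarray      # (T, 3)
    spring_force: np.ndarray    # (T, 3) pN
    direction: str = ""
    k: float = 0.0              # pN/Å
    v: float = 0.0              # m/s
    truncated: bool = False     # ligand left the simulation bounds

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.anchor = np.asarray(self.anchor, float).reshape(-1, 3)
        self.pulled_com = np.asarray(self.pulled_com, float).reshape(-1, 3)
        self.spring_force = np.asarray(self.spring_force, float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.time.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ps": self.time,
            "ax": self.anchor[:, 0], "ay": self.anchor[:, 1], "az": self.anchor[:, 2],
            "cx": self.pulled_com[:, 0], "cy": self.pulled_com[:, 1],
            "cz": self.pulled_com[:, 2],
            "fx_pN": self.spring_force[:, 0], "fy_pN": self.spring_force[:, 1],
            "fz_pN": self.spring_force[:, 2],
        })


def select_pull_atoms(system: ParticleSystem, direction: DirectionSpec,
                      n_atoms: int = 1) -> np.ndarray:
    """Ligand beads with the largest projection onto the pulling direction.

    Projections are measured from the ligand COM, so the selection picks
    the bead(s) leading the chain toward the exit — this mirrors pulling a
    ligand by the atoms nearest the chosen direction, which avoids
    rotating the ligand in the pocket.  Ties break by ascending index.
    """
    lig = system.ligand_indices
    if lig.size == 0:
        raise ValueError("system has no ligand beads")
    if n_atoms < 1 or n_atoms > lig.size:
        raise ValueError(f"n_atoms must be in [1, {lig.size}]")
    pos = system.positions[lig]
    com = np.average(pos, axis=0, weights=system.masses[lig])
    proj = (pos - com) @ direction.vector
    order = np.lexsort((lig, -proj))  # descending projection, ascending index
    return np.sort(lig[order[:n_atoms]])


def run_smd(system: ParticleSystem, state: SimState, direction: DirectionSpec,
            schedule: PullSchedule, seed: Optional[int] = None,
            dt: float = 0.01, temperature: float = 300.0, friction: float = 1.0,
            n_pull_atoms: int = 1, traj_every: int = 0
            ) -> Tuple[ForceRecord, Optional[Trajectory]]:
    """One constant-velocity pull; returns the force record (and frames).

    The spring attaches to the COM of the ``n_pull_atoms`` beads selected
    by :func:`select_pull_atoms`; the anchor starts at that COM and moves
    at ``schedule.v`` along ``direction``.  If the pulled COM leaves the
    confining container, the record is truncated and flagged.
    """
    pull_idx = select_pull_atoms(system, direction, n_pull_atoms)
    masses = system.masses[pull_idx]
    anchor0 = np.average(state.positions[pull_idx], axis=0, weights=masses)
    anchor_vel = schedule.v_ang_per_ps * direction.vector
    n_steps = int(round(schedule.duration / dt))

    work = state.copy()
    if seed is not None:
        work.rng = np.random.Generator(np.random.PCG64(seed))
        work.rng_label = f"pcg64:{seed}"

    new_state, records, traj = _propagate(
        system, work, n_steps, dt, temperature, friction,
        pull_idx=pull_idx.astype(np.int64), k_spring=schedule.k_kcal,
        anchor0=anchor0, anchor_vel=anchor_vel,
        record_every=schedule.record_every, traj_every=traj_every)

    record = ForceRecord(
        time=records["t"], anchor=records["anchor"], pulled_com=records["com"],
        spring_force=records["force"] * KCAL_PER_MOL_ANG_TO_PN,
        direction=direction.label, k=schedule.k, v=schedule.v)

    # escape check against the confining sphere
    out = np.linalg.norm(record.pulled_com - system.container_center, axis=1) \
        > system.container_radius
    if out.any():
        cut = int(np.nonzero(out)[0][0])
        record = ForceRecord(record.time[:cut], record.anchor[:cut],
                             record.pulled_com[:cut], record.spring_force[:cut],
                             direction=record.direction, k=record.k, v=record.v,
                             truncated=True)
    return record, traj
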