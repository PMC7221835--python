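"""Ligand–receptor interaction-energy profiles.

The nonbonded interaction energy between two disjoint particle groups is
split into its electrostatic (Coulomb) and van der Waals (Lennard-Jones)
contributions; the total is formed as E_elec + E_vdw in that fixed order
so the decomposition identity holds exactly at every sample.  The same
cutoff/switching as the dynamics engine is used by default; ``exact=True``
disables the cutoff for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import SimState, Trajectory
from .toy_receptor import ParticleSystem
from .units import COULOMB_K


def _switch_values(r2: np.ndarray, ron2: float, roff2: float) -> np.ndarray:
    s = np.zeros_like(r2)
    s[r2 <= ron2] = 1.0
    mid = (r2 > ron2) & (r2 < roff2)
    a = roff2 - r2[mid]
    s[mid] = a * a * (roff2 + 2.0 * r2[mid] - 3.0 * ron2) / (roff2 - ron2) ** 3
    return s


def _resolve_group(system: ParticleSystem, group) -> np.ndarray:
    if isinstance(group, str):
        idx = system.group_indices(group)
    else:
        idx = np.asarray(group, dtype=np.int64)
    if idx.size == 0:
        raise ValueError(f"group {group!r} selects no particles")
    return idx


def interaction_energy_positions(system: ParticleSystem, positions: np.ndarray,
                                 idx_a: np.ndarray, idx_b: np.ndarray,
                                 exact: bool = False) -> Tuple[float, float]:
    """(E_elec, E_vdw) in kcal/mol between index groups at given positions."""
    pa = positions[idx_a]
    pb = positions[idx_b]
    d = pa[:, None, :] - pb[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", d, d)
    r2 = np.maximum(r2, 1e-12)
    if exact:
        s = np.ones_like(r2)
    else:
        roff2 = system.cutoff ** 2
        ron2 = system.switch_on ** 2
        s = _switch_values(r2, ron2, roff2)
    r = np.sqrt(r2)
    qq = np.outer(system.charges[idx_a], system.charges[idx_b])
    e_elec = float(np.sum(COULOMB_K * qq / r * s))
    sij = 0.5 * (system.lj_sigma[idx_a][:, None] + system.lj_sigma[idx_b][None, :])
    eij = np.sqrt(np.outer(system.lj_epsilon[idx_a], system.lj_epsilon[idx_b]))
    sr6 = (sij * sij / r2) ** 3
    e_vdw = float(np.sum(4.0 * eij * (sr6 * sr6 - sr6) * s))
    return e_elec, e_vdw


def interaction_energy(system: ParticleSystem, state, group_a, group_b,
                       exact: bool = False) -> Tuple[float, float]:
    """Pairwise (E_elec, E_vdw) between two disjoint groups, kcal/mol.

    ``state`` may be a :class:`SimState` or a bare (N, 3) position array;
    groups are label strings or index arrays.  Intra-group terms are
    excluded; the result is symmetric in group order.
    """
    idx_a = _resolve_group(system, group_a)
    idx_b = _resolve_group(system, group_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("groups overlap; interaction energy requires disjoint groups")
    positions = state.positions if isinstance(state, SimState) else np.asarray(state)
    if positions.shape != (system.n_particles, 3):
        raise ValueError(f"positions must have shape ({system.n_particles}, 3)")
    return interaction_energy_positions(system, positions, idx_a, idx_b, exact=exact)


@dataclass
class EnergyProfile:
    """Interaction-energy time series with exact elec/vdW decomposition."""

    time: np.ndarray       # ps
    e_elec: np.ndarray     # kcal/mol
    e_vdw: np.ndarray      # kcal/mol

    @property
    def e_total(self) -> np.ndarray:
        return self.e_elec + self.e_vdw

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ps": self.time, "E_elec": self.e_elec,
                             "E_vdw": self.e_vdw, "E_total": self.e_total})

    def smoothed(self, window: int = 50) -> "EnergyProfile":
        """Running-mean smoothed copy (window in samples)."""
        if window < 2 or len(self.time) < window:
            return EnergyProfile(self.time.copy(), self.e_elec.copy(),
                                 self.e_vdw.copy())
        kern = np.ones(window) / window
        sm = lambda x: np.convolve(x, kern, mode="valid")
        n = len(sm(self.e_elec))
        return EnergyProfile(self.time[window - 1:][:n], sm(self.e_elec),
                             sm(self.e_vdw))


def energy_profile(system: ParticleSystem, trajectory: Trajectory, group_a,
                   group_b, stride: int = 1, exact: bool = False) -> EnergyProfile:
    """Interaction-energy profile along a trajectory, one sample per frame."""
    idx_a = _resolve_group(system, group_a)
    idx_b = _resolve_group(system, group_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("groups overlap; interaction energy requires disjoint groups")
    frames = trajectory.frames[::stride]
    times = trajectory.times[::stride]
    e_el = np.empty(frames.shape[0])
    e_vw = np.empty(frames.shape[0])
    for k, frame in enumerate(frames):
        if frame.shape != (system.n_particles, 3):
            raise ValueError(
                f"frame {k * stride} has shape {frame.shape}, expected "
                f"({system.n_particles}, 3)")
        e_el[k], e_vw[k] = interaction_energy_positions(system, frame, idx_a,
                                                        idx_b, exact=exact)
    return EnergyProfile(times.copy(), e_el, e_vw)
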