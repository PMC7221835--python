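"""Pulling-work integration, maximal force, replicate aggregation, ranking.

The pull-out work is the line integral W = ∫ F⃗·dr⃗ of the recorded spring
force along the pulled-COM path, evaluated as the componentwise
trapezoidal sum

    W ≈ Σᵢ (Fx(i)+Fx(i+1))/2·Δxᵢ + (Fy(i)+Fy(i+1))/2·Δyᵢ + (Fz(i)+Fz(i+1))/2·Δzᵢ

with displacement taken from the pulled COM (not the anchor, which would
count spring stretch as travelled distance).  The maximal force — the
largest |F⃗| during a pull — serves as a friction/steric-barrier proxy:
the favoured exit pathway is the one with the smallest mean work, and in
practice also the smallest maximal force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .smd import ForceRecord
from .units import work_pn_ang_to_kcal


def _validate(record: ForceRecord) -> None:
    if len(record) < 2:
        raise ValueError("force record needs at least 2 samples to integrate")
    if not np.all(np.diff(record.time) > 0):
        raise ValueError("force record times must be strictly increasing")


def cumulative_work(record: ForceRecord) -> np.ndarray:
    """Running componentwise trapezoidal work, pN·Å, one value per sample."""
    _validate(record)
    f = record.spring_force
    dr = np.diff(record.pulled_com, axis=0)
    seg = 0.5 * (f[:-1] + f[1:]) * dr  # (T-1, 3) componentwise trapezoids
    return np.concatenate([[0.0], np.cumsum(seg.sum(axis=1))])


def integrate_work(record: ForceRecord) -> float:
    """Total pull-out work, pN·Å (componentwise trapezoidal sum)."""
    return float(cumulative_work(record)[-1])


def integrate_work_kcal(record: ForceRecord) -> float:
    """Total pull-out work in kcal/mol."""
    return work_pn_ang_to_kcal(integrate_work(record))


def max_force(record: ForceRecord) -> float:
    """Largest spring-force magnitude |F⃗| during the pull, pN."""
    if len(record) == 0:
        raise ValueError("empty force record")
    return float(np.linalg.norm(record.spring_force, axis=1).max())


def com_displacement(record: ForceRecord) -> np.ndarray:
    """Cumulative path length of the pulled COM, Å, per sample."""
    steps = np.linalg.norm(np.diff(record.pulled_com, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class WorkProfile:
    """Per-repeat work curves and totals for one pulling direction."""

    direction: str
    works_pn_ang: List[float] = field(default_factory=list)
    max_forces_pn: List[float] = field(default_factory=list)
    cumulative: List[np.ndarray] = field(default_factory=list)   # pN·Å vs sample
    displacement: List[np.ndarray] = field(default_factory=list)  # Å vs sample
    times: List[np.ndarray] = field(default_factory=list)

    @property
    def works_kcal(self) -> List[float]:
        return [work_pn_ang_to_kcal(w) for w in self.works_pn_ang]

    @property
    def n_repeats(self) -> int:
        return len(self.works_pn_ang)


def work_profile(direction: str, records: Sequence[ForceRecord]) -> WorkProfile:
    """Build a :class:`WorkProfile` from repeat force records."""
    prof = WorkProfile(direction)
    for rec in records:
        if rec.direction and rec.direction != direction:
            raise ValueError(
                f"record labelled {rec.direction!r} mixed into direction {direction!r}")
        cum = cumulative_work(rec)
        prof.works_pn_ang.append(float(cum[-1]))
        prof.max_forces_pn.append(max_force(rec))
        prof.cumulative.append(cum)
        prof.displacement.append(com_displacement(rec))
        prof.times.append(rec.time.copy())
    return prof


@dataclass(frozen=True)
class DirectionStats:
    """Replicate-aggregated work and max-force for one direction."""

    direction: str
    n_repeats: int
    mean_work_kcal: float
    sd_work_kcal: float
    mean_max_force_pn: float
    sd_max_force_pn: float
    sd_degenerate: bool  # single repeat: SD reported as 0 with this flag


@dataclass
class DirectionComparison:
    """Aggregated statistics for all directions of one experiment."""

    entries: List[DirectionStats]

    def to_dataframe(self) -> pd.DataFrame:
        ranked = rank_pathways(self)[0]
        rank = {label: i + 1 for i, label in enumerate(ranked)}
        rows = [{
            "direction": e.direction, "n_repeats": e.n_repeats,
            "mean_W_kcal": e.mean_work_kcal, "sd_W_kcal": e.sd_work_kcal,
            "mean_Fmax_pN": e.mean_max_force_pn, "sd_Fmax_pN": e.sd_max_force_pn,
            "rank": rank[e.direction],
        } for e in self.entries]
        return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)

    def __getitem__(self, direction: str) -> DirectionStats:
        for e in self.entries:
            if e.direction == direction:
                return e
        raise KeyError(direction)


def aggregate_direction(profiles: Sequence[WorkProfile]) -> DirectionStats:
    """Mean and sample SD of total work and max force over repeats.

    Accepts one or more profiles for the *same* direction (they are
    pooled); a single pooled repeat yields SD 0 with ``sd_degenerate``.
    """
    labels = {p.direction for p in profiles}
    if len(labels) != 1:
        raise ValueError(f"mixed direction labels in aggregation: {sorted(labels)}")
    works = np.array([w for p in profiles for w in p.works_kcal])
    fmax = np.array([f for p in profiles for f in p.max_forces_pn])
    if works.size == 0:
        raise ValueError("no repeats to aggregate")
    degenerate = works.size < 2
    sd_w = 0.0 if degenerate else float(np.std(works, ddof=1))
    sd_f = 0.0 if degenerate else float(np.std(fmax, ddof=1))
    return DirectionStats(labels.pop(), int(works.size), float(works.mean()),
                          sd_w, float(fmax.mean()), sd_f, degenerate)


def _equivalent(a: DirectionStats, b: DirectionStats) -> bool:
    """Means within the larger of the two SDs — statistically equivalent."""
    return abs(a.mean_work_kcal - b.mean_work_kcal) <= max(a.sd_work_kcal,
                                                           b.sd_work_kcal)


def rank_pathways(comparison: DirectionComparison) -> Tuple[List[str], dict]:
    """Rank directions by mean work; verdict names the favoured pathway.

    Primary key is ascending mean work.  When two directions are
    statistically equivalent (means within the larger SD), the one with
    the smaller mean maximal force ranks first, then label order.
    """
    entries = sorted(comparison.entries,
                     key=lambda e: (e.mean_work_kcal, e.direction))
    if len(entries) < 2:
        raise ValueError("ranking needs at least 2 directions")
    # bubble equivalent adjacent pairs by the max-force tie-break
    changed = True
    while changed:
        changed = False
        for i in range(len(entries) - 1):
            a, b = entries[i], entries[i + 1]
            if _equivalent(a, b):
                key_a = (a.mean_max_force_pn, a.direction)
                key_b = (b.mean_max_force_pn, b.direction)
                if key_b < key_a:
                    entries[i], entries[i + 1] = b, a
                    changed = True
    order = [e.direction for e in entries]
    winner, runner = entries[0], entries[1]
    equivalent = _equivalent(winner, runner)
    verdict = {
        "winner": winner.direction,
        "runner_up": runner.direction,
        "equivalent_pair": equivalent,
        "summary": (
            f"minimum-work pathway: {winner.direction} "
            f"(mean W = {winner.mean_work_kcal:.2f} kcal/mol, "
            f"mean Fmax = {winner.mean_max_force_pn:.1f} pN)"
            + (f"; statistically equivalent to {runner.direction}"
               if equivalent else "")
        ),
    }
    return order, verdict
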