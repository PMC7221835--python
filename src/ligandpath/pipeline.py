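"""Orchestration: config schema and the two end-to-end experiments.

``run_smd_compare`` reproduces the multi-direction pulling comparison
(directions × repeats, work integration, ranking verdict);
``run_sumd`` runs a supervised entrance simulation with energy profiling.
Both are config-first and fully seeded; every replicate's seed is written
to the output manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as lio
from .dynamics import SimulationBlowUpError, initial_state
from .energetics import energy_profile
from .pose import center_of_mass, pose_distance
from .smd import DirectionSpec, ForceRecord, PullSchedule, run_smd, standard_directions
from .sumd import SuMDConfig, SuMDResult, distance_series, supervise
from .toy_receptor import (LigandSpec, ParticleSystem, ReceptorLayout,
                           build_system, place_ligand, widened_layout)
from .work import (DirectionComparison, aggregate_direction, rank_pathways,
                   work_profile)

logger = logging.getLogger("ligandpath")


class ConfigError(ValueError):
    """Invalid run configuration; the message carries the field path."""


def _build_dataclass(cls, data: dict, path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"config error at {path}: unknown field(s) "
                          f"{sorted(unknown)}; known: {sorted(fields)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config error at {path}: {exc}") from exc


@dataclass(frozen=True)
class DynamicsParams:
    dt: float = 0.01          # ps
    temperature: float = 300.0  # K
    friction: float = 1.0     # 1/ps


@dataclass(frozen=True)
class SMDParams:
    k: float = 70.0           # pN/Å
    v: float = 15.0           # m/s (toy default; reference protocol uses 0.3)
    duration: float = 120.0   # ps
    record_every: int = 10
    repeats: int = 3          # replicates per direction
    n_pull_atoms: int = 1
    directions: Optional[List[str]] = None  # None -> the standard five

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def schedule(self) -> PullSchedule:
        return PullSchedule(k=self.k, v=self.v, duration=self.duration,
                            record_every=self.record_every)


@dataclass(frozen=True)
class SuMDParams:
    arrival_radius: float = 4.0
    slice_length: int = 100
    epsilon: float = 0.1
    max_consecutive_rejects: int = 50
    max_total_steps: int = 300_000
    record_every: int = 10
    start_site: str = "outside_gate"
    start_direction: str = "TM1-TM7"
    orientation: str = "tail_first"
    site_center: Optional[List[float]] = None  # None -> pocket center


@dataclass(frozen=True)
class RunConfig:
    layout: ReceptorLayout = field(default_factory=ReceptorLayout)
    ligand: LigandSpec = field(default_factory=LigandSpec)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    smd: SMDParams = field(default_factory=SMDParams)
    sumd: SuMDParams = field(default_factory=SuMDParams)
    seed: int = 1
    outdir: str = "results/run"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - {"layout", "ligand", "dynamics", "smd", "sumd",
                               "seed", "outdir"}
        if unknown:
            raise ConfigError(f"config error: unknown top-level field(s) "
                              f"{sorted(unknown)}")
        layout_data = dict(data.get("layout") or {})
        widen_gate = layout_data.pop("widen_gate", None)
        widen_factor = layout_data.pop("widen_factor", 1.5)
        for key in ("gap_widths", "pocket_center", "membrane_z_range"):
            if key in layout_data:
                layout_data[key] = tuple(layout_data[key])
        layout = _build_dataclass(ReceptorLayout, layout_data, "layout")
        if widen_gate:
            layout = widened_layout(layout, gate_label=widen_gate,
                                    factor=widen_factor)
        ligand_data = dict(data.get("ligand") or {})
        if isinstance(ligand_data.get("masses"), list):
            ligand_data["masses"] = tuple(ligand_data["masses"])
        return cls(
            layout=layout,
            ligand=_build_dataclass(LigandSpec, ligand_data, "ligand"),
            dynamics=_build_dataclass(DynamicsParams,
                                      dict(data.get("dynamics") or {}), "dynamics"),
            smd=_build_dataclass(SMDParams, dict(data.get("smd") or {}), "smd"),
            sumd=_build_dataclass(SuMDParams, dict(data.get("sumd") or {}), "sumd"),
            seed=int(data.get("seed", 1)),
            outdir=str(data.get("outdir", "results/run")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(lio.load_yaml_config(path))


def default_config(seed: int = 1, outdir: str = "results/run") -> RunConfig:
    """The standard toy experiment: widest gate engineered at TM1–TM7."""
    return RunConfig(layout=widened_layout(), seed=seed, outdir=outdir)


def _replicate_seed(base_seed: int, direction_index: int, repeat: int) -> int:
    """Deterministic per-replicate seed, kept below 2³¹."""
    return (base_seed % 1_000_000) * 1000 + direction_index * 100 + repeat


# --------------------------------------------------------------------------
# commands
# --------------------------------------------------------------------------


def run_build(config: RunConfig, outdir=None) -> Dict[str, str]:
    """Build the system and write XYZ + topology + manifest; idempotent."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    system = build_system(config.layout, config.ligand, seed=config.seed)
    xyz = out / "system.xyz"
    topo = out / "topology.json"
    lio.write_xyz(xyz, system, comment=f"ligandpath system seed={config.seed}")
    lio.write_topology(topo, system)
    manifest = {
        "command": "build", "seed": config.seed,
        "n_particles": system.n_particles,
        "realized_gap_widths_A": config.layout.realized_gap_widths().tolist(),
        "gate_labels": list(config.layout.gate_labels()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"xyz": str(xyz), "topology": str(topo)}


def run_smd_compare(config: RunConfig, outdir=None, make_plots: bool = False):
    """Directions × repeats pulling comparison with ranked verdict.

    Returns (comparison, verdict, records).  Failed replicates (dynamics
    blow-up) are logged and excluded; a direction that loses all its
    replicates aborts the job.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    system = build_system(config.layout, config.ligand, seed=config.seed)
    if config.smd.directions is None:
        directions = standard_directions(config.layout)
    else:
        vecs = config.layout.exit_direction_vectors(standard_five=False)
        directions = [DirectionSpec(lbl, tuple(vecs[lbl]))
                      for lbl in config.smd.directions]
    schedule = config.smd.schedule()
    dyn = config.dynamics

    records: Dict[str, List[ForceRecord]] = {}
    seeds_used: Dict[str, List[int]] = {}
    for d_idx, direction in enumerate(directions):
        records[direction.label] = []
        seeds_used[direction.label] = []
        placed = place_ligand(system, "bound", orientation="tail_first",
                              direction=direction, seed=config.seed)
        for rep in range(config.smd.repeats):
            seed = _replicate_seed(config.seed, d_idx, rep)
            state = initial_state(placed, temperature=dyn.temperature, seed=seed)
            try:
                rec, _ = run_smd(placed, state, direction, schedule,
                                 dt=dyn.dt, temperature=dyn.temperature,
                                 friction=dyn.friction,
                                 n_pull_atoms=config.smd.n_pull_atoms)
            except SimulationBlowUpError as exc:
                logger.warning("replicate %s/%d failed and is excluded: %s",
                               direction.label, rep, exc)
                continue
            records[direction.label].append(rec)
            seeds_used[direction.label].append(seed)
            lio.write_force_record_csv(rec, out / f"smd_{direction.label}_rep{rep}.csv")
        if not records[direction.label]:
            raise RuntimeError(
                f"direction {direction.label} lost all {config.smd.repeats} "
                f"replicates")

    profiles = {lbl: work_profile(lbl, recs) for lbl, recs in records.items()}
    comparison = DirectionComparison(
        [aggregate_direction([prof]) for prof in profiles.values()])
    order, verdict = rank_pathways(comparison)

    comparison.to_dataframe().to_csv(out / "comparison.csv", index=False)
    (out / "verdict.json").write_text(json.dumps(
        {**verdict, "ranking": order}, indent=2))
    (out / "manifest.json").write_text(json.dumps({
        "command": "smd-compare", "seed": config.seed,
        "schedule": dataclasses.asdict(schedule),
        "dynamics": dataclasses.asdict(dyn),
        "replicate_seeds": seeds_used,
    }, indent=2))
    if make_plots:
        from .plots import plot_direction_comparison
        plot_direction_comparison(records, out / "smd_comparison.png")
    return comparison, verdict, records


def run_sumd(config: RunConfig, outdir=None, make_plots: bool = False,
             reference_poses: Optional[Dict[str, np.ndarray]] = None) -> SuMDResult:
    """Supervised ligand-entrance run with energy profile and artifacts."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    system = build_system(config.layout, config.ligand, seed=config.seed)
    sp = config.sumd
    placed = place_ligand(system, sp.start_site, orientation=sp.orientation,
                          direction=sp.start_direction, seed=config.seed)
    site = (tuple(sp.site_center) if sp.site_center is not None
            else tuple(config.layout.pocket_center))
    sumd_cfg = SuMDConfig(
        site_center=site, arrival_radius=sp.arrival_radius,
        slice_length=sp.slice_length, epsilon=sp.epsilon,
        max_consecutive_rejects=sp.max_consecutive_rejects,
        max_total_steps=sp.max_total_steps, base_seed=config.seed,
        dt=config.dynamics.dt, temperature=config.dynamics.temperature,
        friction=config.dynamics.friction, record_every=sp.record_every)
    state = initial_state(placed, temperature=config.dynamics.temperature,
                          seed=config.seed)
    result = supervise(placed, state, sumd_cfg)

    result.attempts.to_csv(out / "attempt_log.csv", index=False)
    distance_series(result).to_csv(out / "distance_series.csv", index=False)
    lio.write_xyz_trajectory(out / "trajectory.xyz", result.trajectory,
                             placed.groups)
    profile = energy_profile(placed, result.trajectory,
                             placed.ligand_indices, placed.scaffold_indices)
    profile.to_dataframe().to_csv(out / "energy_profile.csv", index=False)

    manifest = {
        "command": "sumd", "seed": config.seed,
        "termination": result.termination,
        "restart_count": result.restart_count,
        "total_steps": result.total_steps,
        "sumd": dataclasses.asdict(sp),
        "dynamics": dataclasses.asdict(config.dynamics),
    }
    if reference_poses:
        lig = placed.ligand_indices
        final_pose = result.final_state.positions[lig]
        masses = placed.masses[lig]
        rows = [{"reference": name,
                 "distance_A": pose_distance(final_pose, pose, masses)}
                for name, pose in reference_poses.items()]
        pd.DataFrame(rows).to_csv(out / "pose_distances.csv", index=False)
        manifest["pose_references"] = sorted(reference_poses)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if make_plots:
        from .plots import plot_energy_profile
        plot_energy_profile(profile, out / "energy_profile.png")
    return result
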