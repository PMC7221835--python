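"""File formats: XYZ + topology sidecar, force-record CSV, SMD log dialect.

Systems are written as plain XYZ (short group tags in the element column)
with a JSON topology sidecar holding charges, LJ parameters, bonds,
restraints and layout metadata.  Force records round-trip through a CSV
with a fixed header and through a NAMD-style text dialect of
``SMD <step> <cx> <cy> <cz> <fx> <fy> <fz>`` lines for interoperability
with logs produced by real pulling engines.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .smd import ForceRecord
from .toy_receptor import LigandSpec, ParticleSystem, ReceptorLayout

TOPOLOGY_FORMAT = "ligandpath-topology-1"

_GROUP_TAGS = {"membrane": "M", "plug": "P", "ligand-head": "LH",
               "ligand-tail": "LT"}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _group_tag(label: str) -> str:
    if label.startswith("helix-"):
        return "H" + label.split("-", 1)[1]
    return _GROUP_TAGS.get(label, label[:4].upper())


def write_xyz(path, system_or_positions, groups=None, comment: str = "",
              append: bool = False) -> None:
    """Write one XYZ frame (element-like group tags + positions, Å)."""
    if isinstance(system_or_positions, ParticleSystem):
        positions = system_or_positions.positions
        groups = system_or_positions.groups
    else:
        positions = np.asarray(system_or_positions)
        if groups is None:
            groups = np.array(["X"] * positions.shape[0], dtype=object)
    lines = [str(positions.shape[0]), comment]
    for g, (x, y, z) in zip(groups, positions):
        lines.append(f"{_group_tag(str(g)):<6s} {x:18.10f} {y:18.10f} {z:18.10f}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def write_xyz_trajectory(path, trajectory, groups) -> None:
    """Write trajectory frames as concatenated XYZ blocks."""
    first = True
    for t, frame in zip(trajectory.times, trajectory.frames):
        write_xyz(path, frame, groups=groups, comment=f"t_ps={t:.6f}",
                  append=not first)
        first = False


def read_xyz(path):
    """Read the first XYZ frame: (tags, positions)."""
    lines = Path(path).read_text().splitlines()
    try:
        n = int(lines[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:1: expected atom count") from exc
    tags, pos = [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{path}:{ln}: expected 'tag x y z', got {line!r}")
        tags.append(parts[0])
        pos.append([float(p) for p in parts[1:]])
    if len(pos) != n:
        raise ParseError(f"{path}: header promises {n} atoms, found {len(pos)}")
    return np.array(tags), np.array(pos)


def read_xyz_trajectory(path):
    """Read all XYZ frames: (tags, times, frames (F,N,3)).

    Frame times are taken from ``t_ps=`` comments when present, else the
    frame index.
    """
    lines = Path(path).read_text().splitlines()
    pos_frames, times, tags = [], [], None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = float(comment.split("t_ps=")[1].split()[0]) if "t_ps=" in comment \
            else float(frame_no)
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: truncated frame at line {i + 1}")
        frame_tags, pos = [], []
        for ln, line in enumerate(block, start=i + 3):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 'tag x y z'")
            frame_tags.append(parts[0])
            pos.append([float(p) for p in parts[1:]])
        if tags is None:
            tags = np.array(frame_tags)
        pos_frames.append(pos)
        times.append(t)
        frame_no += 1
        i += 2 + n
    if not pos_frames:
        raise ParseError(f"{path}: no XYZ frames found")
    return tags, np.array(times), np.array(pos_frames)


# --------------------------------------------------------------------------
# topology sidecar
# --------------------------------------------------------------------------


def write_topology(path, system: ParticleSystem) -> None:
    payload = {
        "format": TOPOLOGY_FORMAT,
        "charges": system.charges.tolist(),
        "lj_epsilon": system.lj_epsilon.tolist(),
        "lj_sigma": system.lj_sigma.tolist(),
        "masses": system.masses.tolist(),
        "bonds": system.bonds.tolist(),
        "bond_k": system.bond_k.tolist(),
        "bond_r0": system.bond_r0.tolist(),
        "restrained": system.restrained.astype(int).tolist(),
        "reference_positions": system.reference_positions.tolist(),
        "groups": [str(g) for g in system.groups],
        "restraint_k": system.restraint_k,
        "container_center": system.container_center.tolist(),
        "container_radius": system.container_radius,
        "container_k": system.container_k,
        "cutoff": system.cutoff,
        "switch_on": system.switch_on,
        "layout": dataclasses.asdict(system.layout) if system.layout else None,
        "ligand": dataclasses.asdict(system.ligand) if system.ligand else None,
    }
    Path(path).write_text(json.dumps(payload))


def read_system(xyz_path, topology_path) -> ParticleSystem:
    """Reconstruct a :class:`ParticleSystem` from XYZ + topology files."""
    payload = json.loads(Path(topology_path).read_text())
    if payload.get("format") != TOPOLOGY_FORMAT:
        raise ParseError(f"{topology_path}: not a {TOPOLOGY_FORMAT} file")
    _, positions = read_xyz(xyz_path)
    layout = payload.get("layout")
    ligand = payload.get("ligand")
    if layout:
        for key in ("gap_widths", "pocket_center", "membrane_z_range"):
            layout[key] = tuple(layout[key])
        layout = ReceptorLayout(**layout)
    if ligand:
        if isinstance(ligand["masses"], list):
            ligand["masses"] = tuple(ligand["masses"])
        ligand = LigandSpec(**ligand)
    return ParticleSystem(
        positions=positions,
        charges=np.array(payload["charges"]),
        lj_epsilon=np.array(payload["lj_epsilon"]),
        lj_sigma=np.array(payload["lj_sigma"]),
        masses=np.array(payload["masses"]),
        bonds=np.array(payload["bonds"], dtype=np.int64).reshape(-1, 2),
        bond_k=np.array(payload["bond_k"]),
        bond_r0=np.array(payload["bond_r0"]),
        restrained=np.array(payload["restrained"], dtype=bool),
        reference_positions=np.array(payload["reference_positions"]),
        groups=np.array(payload["groups"], dtype=object),
        restraint_k=payload["restraint_k"],
        container_center=np.array(payload["container_center"]),
        container_radius=payload["container_radius"],
        container_k=payload["container_k"],
        cutoff=payload["cutoff"],
        switch_on=payload["switch_on"],
        layout=layout,
        ligand=ligand,
    )


# --------------------------------------------------------------------------
# force records
# --------------------------------------------------------------------------

FORCE_CSV_COLUMNS = ["t_ps", "ax", "ay", "az", "cx", "cy", "cz",
                     "fx_pN", "fy_pN", "fz_pN"]


def write_force_record_csv(record: ForceRecord, path) -> None:
    record.to_dataframe().to_csv(path, index=False)


def read_force_record_csv(path, direction: str = "") -> ForceRecord:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FORCE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing force-record columns {sorted(missing)}")
    return ForceRecord(
        time=df["t_ps"].to_numpy(),
        anchor=df[["ax", "ay", "az"]].to_numpy(),
        pulled_com=df[["cx", "cy", "cz"]].to_numpy(),
        spring_force=df[["fx_pN", "fy_pN", "fz_pN"]].to_numpy(),
        direction=direction)


def write_namd_smd_log(record: ForceRecord, path, dt: float = 0.01) -> None:
    """Write the NAMD-style dialect: ``SMD step cx cy cz fx fy fz``.

    The dialect carries no anchor positions and encodes time as a step
    count (``step = round(t/dt)``); forces are in pN as recorded.
    """
    lines = []
    for t, com, f in zip(record.time, record.pulled_com, record.spring_force):
        step = int(round(t / dt))
        vals = " ".join(repr(float(v)) for v in (*com, *f))
        lines.append(f"SMD {step} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_namd_smd_log(path, dt: float = 0.01, direction: str = "") -> ForceRecord:
    """Parse the NAMD-style dialect; anchors are filled with NaN."""
    times, coms, forces = [], [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if parts[0] != "SMD":
            raise ParseError(f"{path}:{ln}: expected line to start with 'SMD'")
        if len(parts) != 8:
            raise ParseError(
                f"{path}:{ln}: expected 8 fields (SMD step cx cy cz fx fy fz), "
                f"got {len(parts)}")
        try:
            step = int(parts[1])
            vals = [float(p) for p in parts[2:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: non-numeric field: {exc}") from exc
        times.append(step * dt)
        coms.append(vals[:3])
        forces.append(vals[3:])
    if not times:
        raise ParseError(f"{path}: no SMD lines found")
    n = len(times)
    return ForceRecord(time=np.array(times), anchor=np.full((n, 3), np.nan),
                       pulled_com=np.array(coms), spring_force=np.array(forces),
                       direction=direction)


def parse_smd_log(path, dialect: str, dt: float = 0.01) -> ForceRecord:
    """Read a force record in either supported dialect (``csv`` | ``namd``)."""
    if dialect == "csv":
        return read_force_record_csv(path)
    if dialect == "namd":
        return read_namd_smd_log(path, dt=dt)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'namd'")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def load_yaml_config(path) -> dict:
    """Parse a YAML config; syntax errors report the line number."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark else ""
        raise ParseError(f"{path}: invalid YAML{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return data
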