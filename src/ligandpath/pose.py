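"""Center-of-mass pose distances and per-ligand aggregation.

When a simulated final pose cannot be atom-matched to a crystallographic
ligand (different molecules in the same pocket), an RMSD is undefined;
the COM–COM distance in the shared receptor frame is the standard
fallback.  This module computes those distances and aggregates published
per-ligand tables of them; no superposition is performed, so poses must
already be expressed in a common frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Packaged table of COM distances (Å) between supervised-MD final poses
#: of lipid-receptor agonists and crystallographic ligands of the same
#: receptor, as published for the CB1/S1P1/LPA1 entrance simulations.
REFERENCE_TABLE = "sumd_crystal_com_distances.csv"


def center_of_mass(positions: np.ndarray, masses: np.ndarray,
                   subset: Optional[Sequence[int]] = None) -> np.ndarray:
    """Mass-weighted mean position, Å."""
    pos = np.asarray(positions, float).reshape(-1, 3)
    m = np.asarray(masses, float)
    if subset is not None:
        idx = np.asarray(subset, dtype=np.int64)
        if idx.size == 0:
            raise ValueError("subset must be non-empty")
        pos, m = pos[idx], m[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be > 0")
    return (m[:, None] * pos).sum(axis=0) / total


def pose_distance(pose_a: np.ndarray, pose_b: np.ndarray,
                  masses: np.ndarray) -> float:
    """Euclidean distance between the COMs of two poses of one molecule, Å."""
    return float(np.linalg.norm(center_of_mass(pose_a, masses)
                                - center_of_mass(pose_b, masses)))


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (3.45 → 3.5, −3.45 → −3.5)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


@dataclass
class PoseDistanceTable:
    """Rows of (ligand, reference ligand + source structure, distance Å)."""

    frame: pd.DataFrame  # columns: ligand, reference, pdb_id, distance_A

    def __post_init__(self):
        required = {"ligand", "reference", "pdb_id", "distance_A"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"pose-distance table missing columns: {sorted(missing)}")
        if (self.frame["distance_A"] < 0).any():
            raise ValueError("pose distances must be >= 0")
        dup = self.frame.duplicated(["ligand", "reference", "pdb_id"])
        if dup.any():
            raise ValueError(
                f"duplicate (ligand, reference, pdb_id) rows: "
                f"{self.frame[dup].to_dict('records')}")

    @classmethod
    def from_csv(cls, path) -> "PoseDistanceTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def ligands(self) -> list[str]:
        return sorted(self.frame["ligand"].unique())

    def rows_for(self, ligand_label: str) -> pd.DataFrame:
        rows = self.frame[self.frame["ligand"] == ligand_label]
        if rows.empty:
            raise KeyError(
                f"unknown ligand {ligand_label!r}; available: {self.ligands}")
        return rows


def mean_reference_distance(table: PoseDistanceTable, ligand_label: str,
                            decimals: int = 1) -> float:
    """Mean crystal-reference distance for one ligand, Å.

    Arithmetic mean of that ligand's rows, rounded half away from zero to
    the requested decimals (the rounding convention of published tables).
    """
    rows = table.rows_for(ligand_label)
    return round_half_away(float(rows["distance_A"].mean()), decimals)


def load_reference_table() -> PoseDistanceTable:
    """The packaged SuMD-vs-crystal COM distance table."""
    with resources.files("ligandpath").joinpath("data", REFERENCE_TABLE).open() as fh:
        return PoseDistanceTable(pd.read_csv(fh, comment="#"))
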