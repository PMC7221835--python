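"""Synthetic coarse-grained receptor–membrane–ligand systems.

This module is the package's data generator. It builds a bead model that
reproduces the structural premises of lipid-binding GPCRs at the cheapest
possible resolution:

* a ring of ``n_helices`` rigid vertical pillars (transmembrane-helix
  stand-ins) around a central binding pocket,
* lateral gates between adjacent pillars whose widths are configurable,
  with one gate optionally engineered widest (the TM1–TM7 analog),
* a membrane slab represented by two planar bead sheets with a cavity
  around the helix ring,
* an optional "plug" disc of beads above the pocket modelling the
  N-terminal domain that occludes vertical (extracellular) access, and
* a bead-chain ligand with one charged head bead and a hydrophobic tail.

Because the geometry is synthetic, the ground-truth exit pathway is known
by construction and can be recovered independently of any dynamics by a
rigid energy scan (:func:`ground_truth_barriers`), which serves as the
oracle for the pulling-work ranking experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .units import COULOMB_K


class BuildError(RuntimeError):
    """Raised when a system cannot be constructed without steric clashes."""


# --------------------------------------------------------------------------
# layout / ligand specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReceptorLayout:
    """Geometry of the synthetic helix-ring receptor.

    ``gap_widths`` are relative arc weights for the inter-helix gates: the
    ring circumference is shared between pillar cross-sections and gates in
    proportion to (pillar diameter, gap width); widening one entry widens
    the realized arc of that gate monotonically.  Gate ``i`` (0-based) lies
    between helix ``i+1`` and helix ``i+2`` (1-based, wrapping).
    """

    n_helices: int = 7
    helix_radius: float = 8.0          # Å, ring radius of pillar axes
    gap_widths: Tuple[float, ...] = (2.0,) * 7
    widest_gate: Optional[int] = None  # gate index flagged as engineered widest
    pocket_center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    pocket_radius: float = 4.0
    up_plug: bool = True
    plug_strength: float = 1.0         # scales the plug bead LJ epsilon
    membrane_z_range: Tuple[float, float] = (-6.0, 6.0)

    # bead-model parameters (Å, kcal/mol, amu)
    helix_half_height: float = 8.0
    helix_bead_spacing: float = 2.0
    helix_sigma: float = 5.0
    helix_epsilon: float = 0.25
    membrane_sigma: float = 4.0
    membrane_epsilon: float = 0.20
    membrane_outer_radius: float = 19.0
    membrane_bead_spacing: float = 4.5
    plug_radius: float = 6.0
    plug_sigma: float = 4.0
    plug_z_offset: float = 2.5         # plug disc height above pillar tops
    scaffold_mass: float = 72.0
    restraint_k: float = 5.0           # kcal/mol/Å², scaffold tether
    container_radius: float = 26.0     # Å, flat-bottom confining sphere
    container_k: float = 2.0

    def __post_init__(self) -> None:
        if self.n_helices < 3:
            raise ValueError(f"n_helices must be >= 3, got {self.n_helices}")
        if len(self.gap_widths) != self.n_helices:
            raise ValueError(
                f"gap_widths must have length n_helices={self.n_helices}, "
                f"got {len(self.gap_widths)}"
            )
        if any(g <= 0 for g in self.gap_widths):
            raise ValueError("all gap_widths must be > 0")
        if not self.pocket_radius < self.helix_radius:
            raise ValueError("pocket_radius must be smaller than helix_radius")
        if self.widest_gate is not None:
            if not 0 <= self.widest_gate < self.n_helices:
                raise ValueError(f"widest_gate index {self.widest_gate} out of range")
            g = self.gap_widths
            if g[self.widest_gate] < max(g):
                raise ValueError(
                    "gate flagged widest does not have the largest gap width"
                )

    # -- derived geometry ---------------------------------------------------

    def helix_angles(self) -> np.ndarray:
        """Angular positions of the pillar axes, from cumulative arc weights."""
        d = self.helix_sigma
        arcs = np.array([d + g for g in self.gap_widths], dtype=float)
        scale = 2.0 * np.pi / arcs.sum()
        # pillar i+1 sits after pillar i's half-diameter, gap i, half-diameter
        starts = np.concatenate([[0.0], np.cumsum(arcs)[:-1]])
        return starts * scale

    def gate_angle(self, gate: int) -> float:
        """Bisector angle of gate ``gate`` (between helices gate+1, gate+2)."""
        ang = self.helix_angles()
        d = self.helix_sigma
        arcs = np.array([d + g for g in self.gap_widths], dtype=float)
        scale = 2.0 * np.pi / arcs.sum()
        return float(ang[gate] + 0.5 * arcs[gate] * scale)

    def gate_unit_vector(self, gate: int) -> np.ndarray:
        """Outward unit vector along the bisector of a gate, in the xy plane."""
        a = self.gate_angle(gate)
        return np.array([np.cos(a), np.sin(a), 0.0])

    def gate_label(self, gate: int) -> str:
        a = gate + 1
        b = gate + 2 if gate + 1 < self.n_helices else 1
        lo, hi = sorted((a, b))
        return f"TM{lo}-TM{hi}"

    def gate_labels(self) -> Tuple[str, ...]:
        return tuple(self.gate_label(i) for i in range(self.n_helices))

    def gate_index(self, label: str) -> int:
        for i in range(self.n_helices):
            if self.gate_label(i) == label:
                return i
        raise KeyError(f"unknown gate label {label!r}; known: {self.gate_labels()}")

    def realized_gap_widths(self) -> np.ndarray:
        """Arc width of each gate between pillar surfaces, Å, on the ring."""
        d = self.helix_sigma
        arcs = np.array([dd + g for dd, g in zip([d] * self.n_helices, self.gap_widths)])
        scale = 2.0 * np.pi / arcs.sum()
        return self.helix_radius * arcs * scale - d

    def exit_direction_vectors(self, standard_five: bool = True) -> Dict[str, np.ndarray]:
        """Exit-direction unit vectors: gate bisectors plus the vertical UP.

        With ``standard_five`` (requires 7 helices) returns the five
        directions used in the pulling comparison: TM1–TM7, TM1–TM2, UP,
        TM4–TM5, TM5–TM6.  Otherwise every gate plus UP.
        """
        up = np.array([0.0, 0.0, 1.0])
        if standard_five and self.n_helices == 7:
            order = ["TM1-TM7", "TM1-TM2", "UP", "TM4-TM5", "TM5-TM6"]
            vecs = {self.gate_label(i): self.gate_unit_vector(i) for i in range(7)}
            vecs["UP"] = up
            return {k: vecs[k] for k in order}
        out = {self.gate_label(i): self.gate_unit_vector(i) for i in range(self.n_helices)}
        out["UP"] = up
        return out


def widened_layout(base: Optional[ReceptorLayout] = None, gate_label: str = "TM1-TM7",
                   factor: float = 1.5) -> ReceptorLayout:
    """A layout with one gate widened by ``factor`` and flagged widest."""
    layout = base if base is not None else ReceptorLayout()
    idx = layout.gate_index(gate_label)
    gaps = list(layout.gap_widths)
    gaps[idx] = gaps[idx] * factor
    return replace(layout, gap_widths=tuple(gaps), widest_gate=idx)


@dataclass(frozen=True)
class LigandSpec:
    """Bead-chain ligand: one charged head bead plus a hydrophobic tail.

    Abstracts the shared architecture of lipid-receptor agonists (polar
    phosphate-like head, long alkyl tail).  Bead 0 is the head; beads
    1..n-1 are the tail, connected as a path by harmonic bonds.
    """

    n_beads: int = 4
    head_charge: float = -1.0          # e
    tail_bead_epsilon: float = 0.35    # kcal/mol
    bond_length: float = 2.2           # Å
    bond_k: float = 50.0               # kcal/mol/Å²
    masses: float | Tuple[float, ...] = 40.0
    sigma: float = 3.2
    head_epsilon: float = 0.20

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("ligand needs at least 2 beads (head + tail)")
        if isinstance(self.masses, (tuple, list)) and len(self.masses) != self.n_beads:
            raise ValueError("per-bead masses must match n_beads")

    def mass_array(self) -> np.ndarray:
        if isinstance(self.masses, (tuple, list)):
            return np.asarray(self.masses, dtype=float)
        return np.full(self.n_beads, float(self.masses))


# --------------------------------------------------------------------------
# particle system container
# --------------------------------------------------------------------------


@dataclass
class ParticleSystem:
    """Beads, interactions and group labels for one receptor+ligand system.

    The scaffold (helices, membrane, plug) is harmonically restrained to
    its build positions; the ligand is the only free molecule.  A
    flat-bottom spherical container keeps everything in a finite volume —
    the systems are non-periodic.
    """

    positions: np.ndarray          # (N, 3) Å
    charges: np.ndarray            # (N,) e
    lj_epsilon: np.ndarray         # (N,) kcal/mol
    lj_sigma: np.ndarray           # (N,) Å
    masses: np.ndarray             # (N,) amu
    bonds: np.ndarray              # (M, 2) int
    bond_k: np.ndarray             # (M,) kcal/mol/Å²
    bond_r0: np.ndarray            # (M,) Å
    restrained: np.ndarray         # (N,) bool
    reference_positions: np.ndarray  # (N, 3) restraint anchors
    groups: np.ndarray             # (N,) str labels
    restraint_k: float = 5.0
    container_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    container_radius: float = 1.0e6
    container_k: float = 0.0
    cutoff: float = 12.0           # Å, nonbonded cutoff
    switch_on: float = 10.0        # Å, switching starts here
    layout: Optional[ReceptorLayout] = None
    ligand: Optional[LigandSpec] = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.reference_positions = np.ascontiguousarray(
            self.reference_positions, dtype=np.float64
        )
        n = self.positions.shape[0]
        for name in ("charges", "lj_epsilon", "lj_sigma", "masses"):
            arr = np.ascontiguousarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            setattr(self, name, arr)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_k = np.ascontiguousarray(self.bond_k, dtype=np.float64)
        self.bond_r0 = np.ascontiguousarray(self.bond_r0, dtype=np.float64)
        self.restrained = np.asarray(self.restrained, dtype=bool)
        self.groups = np.asarray(self.groups, dtype=object)
        self.container_center = np.asarray(self.container_center, dtype=np.float64)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def group_indices(self, *labels: str) -> np.ndarray:
        mask = np.isin(self.groups, labels)
        return np.nonzero(mask)[0]

    @property
    def ligand_indices(self) -> np.ndarray:
        return self.group_indices("ligand-head", "ligand-tail")

    @property
    def scaffold_indices(self) -> np.ndarray:
        return np.nonzero(~np.isin(self.groups, ["ligand-head", "ligand-tail"]))[0]

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            charges=self.charges.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            lj_sigma=self.lj_sigma.copy(),
            masses=self.masses.copy(),
            bonds=self.bonds.copy(),
            bond_k=self.bond_k.copy(),
            bond_r0=self.bond_r0.copy(),
            restrained=self.restrained.copy(),
            reference_positions=self.reference_positions.copy(),
            groups=self.groups.copy(),
            restraint_k=self.restraint_k,
            container_center=self.container_center.copy(),
            container_radius=self.container_radius,
            container_k=self.container_k,
            cutoff=self.cutoff,
            switch_on=self.switch_on,
            layout=self.layout,
            ligand=self.ligand,
        )


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------


def _scaffold_beads(layout: ReceptorLayout):
    """Positions + per-bead parameters for helices, membrane and plug."""
    pos, sig, eps, grp = [], [], [], []

    # helix pillars: vertical stacks of overlapping beads
    angles = layout.helix_angles()
    z = np.arange(-layout.helix_half_height, layout.helix_half_height + 1e-9,
                  layout.helix_bead_spacing)
    cx, cy, cz = layout.pocket_center
    for k, a in enumerate(angles):
        x = cx + layout.helix_radius * np.cos(a)
        y = cy + layout.helix_radius * np.sin(a)
        for zz in z:
            pos.append((x, y, cz + zz))
            sig.append(layout.helix_sigma)
            eps.append(layout.helix_epsilon)
            grp.append(f"helix-{k + 1}")

    # membrane: two planar sheets with a cavity around the helix ring
    hole = layout.helix_radius + 0.5 * layout.helix_sigma + 1.0
    for zz in layout.membrane_z_range:
        r = hole
        while r <= layout.membrane_outer_radius + 1e-9:
            n_b = max(1, int(round(2.0 * np.pi * r / layout.membrane_bead_spacing)))
            for j in range(n_b):
                a = 2.0 * np.pi * j / n_b
                pos.append((cx + r * np.cos(a), cy + r * np.sin(a), cz + zz))
                sig.append(layout.membrane_sigma)
                eps.append(layout.membrane_epsilon)
                grp.append("membrane")
            r += layout.membrane_bead_spacing

    # N-terminal plug: bead disc capping the vertical exit
    if layout.up_plug:
        z_plug = cz + layout.helix_half_height + layout.plug_z_offset
        spacing = 3.0
        pos.append((cx, cy, z_plug))
        sig.append(layout.plug_sigma)
        eps.append(layout.plug_strength * layout.helix_epsilon)
        grp.append("plug")
        r = spacing
        while r <= layout.plug_radius + 1e-9:
            n_b = max(1, int(round(2.0 * np.pi * r / spacing)))
            for j in range(n_b):
                a = 2.0 * np.pi * j / n_b
                pos.append((cx + r * np.cos(a), cy + r * np.sin(a), z_plug))
                sig.append(layout.plug_sigma)
                eps.append(layout.plug_strength * layout.helix_epsilon)
                grp.append("plug")
            r += spacing

    return (np.array(pos, dtype=float), np.array(sig), np.array(eps),
            np.array(grp, dtype=object))


def _ligand_axis_positions(ligand: LigandSpec, center: np.ndarray, axis: np.ndarray,
                           orientation: str) -> np.ndarray:
    """Chain bead positions on a line through ``center`` along ``axis``.

    ``axis`` points toward the feature of interest (gate or pocket); with
    ``tail_first`` the tail end of the chain (highest bead index) lies
    furthest along +axis, so the head bead trails.  ``head_first`` is the
    mirror image about ``center``, i.e. the chain reversed about the axis.
    """
    if orientation not in ("tail_first", "head_first"):
        raise ValueError(f"unknown orientation {orientation!r}")
    n = ligand.n_beads
    offsets = (np.arange(n) - 0.5 * (n - 1)) * ligand.bond_length
    sign = 1.0 if orientation == "tail_first" else -1.0
    return center[None, :] + sign * offsets[:, None] * axis[None, :]


def build_system(layout: ReceptorLayout, ligand: LigandSpec, seed: int = 0) -> ParticleSystem:
    """Assemble the full particle system with the ligand bound in the pocket.

    Deterministic for a fixed seed: the scaffold is purely geometric and
    the seed only drives clash-resolving jitter of the ligand placement.
    """
    spos, ssig, seps, sgrp = _scaffold_beads(layout)
    n_s = spos.shape[0]
    n_l = ligand.n_beads

    positions = np.vstack([spos, np.zeros((n_l, 3))])
    lj_sigma = np.concatenate([ssig, np.full(n_l, ligand.sigma)])
    lj_epsilon = np.concatenate([
        seps,
        np.concatenate([[ligand.head_epsilon], np.full(n_l - 1, ligand.tail_bead_epsilon)]),
    ])
    charges = np.zeros(n_s + n_l)
    charges[n_s] = ligand.head_charge
    masses = np.concatenate([np.full(n_s, layout.scaffold_mass), ligand.mass_array()])
    groups = np.concatenate([
        sgrp,
        np.array(["ligand-head"] + ["ligand-tail"] * (n_l - 1), dtype=object),
    ])
    restrained = np.concatenate([np.ones(n_s, bool), np.zeros(n_l, bool)])
    bonds = np.array([(n_s + i, n_s + i + 1) for i in range(n_l - 1)], dtype=np.int64)

    system = ParticleSystem(
        positions=positions,
        charges=charges,
        lj_epsilon=lj_epsilon,
        lj_sigma=lj_sigma,
        masses=masses,
        bonds=bonds,
        bond_k=np.full(n_l - 1, ligand.bond_k),
        bond_r0=np.full(n_l - 1, ligand.bond_length),
        restrained=restrained,
        reference_positions=positions.copy(),
        groups=groups,
        restraint_k=layout.restraint_k,
        container_center=np.asarray(layout.pocket_center, dtype=float),
        container_radius=layout.container_radius,
        container_k=layout.container_k,
        layout=layout,
        ligand=ligand,
    )
    return place_ligand(system, "bound", seed=seed)


def place_ligand(system: ParticleSystem, site: str, orientation: str = "tail_first",
                 direction=None, seed: int = 0) -> ParticleSystem:
    """Re-place the ligand chain at a named site; returns a new system.

    Sites: ``bound`` (pocket center, axis toward ``direction`` or the
    flagged widest gate), ``outside_gate`` (just outside a lateral gate,
    mid-membrane; ``direction`` selects the gate), ``extracellular``
    (above the plug on the pocket axis).  ``direction`` may be a gate
    label, a unit 3-vector, or an object with a ``unit_vector`` attribute.
    Steric clashes against the scaffold are resolved by up to 100 seeded
    jitter retries; failure raises :class:`BuildError` naming the site and
    the closest offending pair.
    """
    layout = system.layout
    ligand = system.ligand
    if layout is None or ligand is None:
        raise ValueError("system lacks layout/ligand metadata; cannot place ligand")

    u = _resolve_direction(layout, direction)
    center = np.asarray(layout.pocket_center, dtype=float)
    if site == "bound":
        chain_center, axis = center, u
    elif site == "outside_gate":
        chain_center = center + u * (layout.helix_radius + 4.0)
        axis = -u  # pointing inward, toward the gate
    elif site == "extracellular":
        z_top = layout.helix_half_height + layout.plug_z_offset + 4.0
        chain_center = center + np.array([0.0, 0.0, z_top])
        axis = np.array([0.0, 0.0, -1.0])
    else:
        raise ValueError(f"unknown site {site!r}")

    lig_idx = system.ligand_indices
    sc_idx = system.scaffold_indices
    rng = np.random.default_rng(seed)
    clash_floor = 0.5 * float(system.lj_sigma.min())

    new = system.copy()
    for attempt in range(100):
        jitter = np.zeros(3) if attempt == 0 else rng.normal(0.0, 0.4, size=3)
        chain = _ligand_axis_positions(ligand, chain_center + jitter, axis, orientation)
        d = np.linalg.norm(chain[:, None, :] - system.positions[sc_idx][None, :, :], axis=-1)
        if d.min() >= clash_floor:
            new.positions[lig_idx] = chain
            return new
    i, j = np.unravel_index(np.argmin(d), d.shape)
    raise BuildError(
        f"cannot place ligand at site {site!r} without clash: ligand bead {i} "
        f"vs scaffold particle {sc_idx[j]} at {d[i, j]:.2f} Å (< {clash_floor:.2f} Å)"
    )


def _resolve_direction(layout: ReceptorLayout, direction) -> np.ndarray:
    if direction is None:
        gate = layout.widest_gate if layout.widest_gate is not None else 0
        return layout.gate_unit_vector(gate)
    if hasattr(direction, "unit_vector"):
        return np.asarray(direction.unit_vector, dtype=float)
    if isinstance(direction, str):
        if direction == "UP":
            return np.array([0.0, 0.0, 1.0])
        return layout.gate_unit_vector(layout.gate_index(direction))
    v = np.asarray(direction, dtype=float)
    return v / np.linalg.norm(v)


def build_funnel(ligand: Optional[LigandSpec] = None, start_distance: float = 20.0,
                 container_radius: float = 24.0, site_epsilon: float = 8.0,
                 site_sigma: float = 3.5, wall_only: bool = False) -> ParticleSystem:
    """A minimal binding funnel for supervised-entrance experiments.

    One restrained attractor bead marks the binding site at the origin; the
    ligand chain starts ``start_distance`` Å away inside a flat-bottom
    spherical container.  Beyond the nonbonded cutoff the ligand diffuses
    freely, so finding the site is a search problem — the regime where
    distance supervision pays off.  With ``wall_only`` the site bead is
    purely repulsive (ε scaled, site unreachable attractor absent).
    """
    lig = ligand if ligand is not None else LigandSpec(n_beads=3, head_charge=0.0)
    n_l = lig.n_beads
    site_pos = np.zeros((1, 3))
    chain = _ligand_axis_positions(
        lig, np.array([start_distance, 0.0, 0.0]),
        np.array([-1.0, 0.0, 0.0]), "tail_first")
    positions = np.vstack([site_pos, chain])
    eps_site = 0.05 if wall_only else site_epsilon
    return ParticleSystem(
        positions=positions,
        charges=np.zeros(1 + n_l),
        lj_epsilon=np.concatenate([[eps_site], [lig.head_epsilon],
                                   np.full(n_l - 1, lig.tail_bead_epsilon)]),
        lj_sigma=np.concatenate([[site_sigma], np.full(n_l, lig.sigma)]),
        masses=np.concatenate([[1000.0], lig.mass_array()]),
        bonds=np.array([(1 + i, 2 + i) for i in range(n_l - 1)], dtype=np.int64),
        bond_k=np.full(n_l - 1, lig.bond_k),
        bond_r0=np.full(n_l - 1, lig.bond_length),
        restrained=np.array([True] + [False] * n_l),
        reference_positions=positions.copy(),
        groups=np.array(["site", "ligand-head"] + ["ligand-tail"] * (n_l - 1),
                        dtype=object),
        restraint_k=50.0,
        container_center=np.zeros(3),
        container_radius=container_radius,
        container_k=2.0,
        ligand=lig,
    )


# --------------------------------------------------------------------------
# ground-truth oracle
# --------------------------------------------------------------------------


def ground_truth_barriers(layout: ReceptorLayout, ligand: LigandSpec,
                          directions: Optional[Mapping[str, Sequence[float]]] = None,
                          step: float = 0.2, r_max: float = 18.0) -> Dict[str, float]:
    """Static exit barriers by rigid ligand translation along each exit line.

    For every direction the ligand is placed bound (tail first, aimed at
    that direction) and translated rigidly outward; the barrier is the
    maximum ligand–scaffold nonbonded interaction energy along the line,
    relative to the starting pose.  Deterministic, dynamics-free — this is
    the oracle the pulling-work ranking is checked against.
    """
    from .energetics import interaction_energy_positions

    if directions is None:
        directions = layout.exit_direction_vectors(standard_five=layout.n_helices == 7)

    system = build_system(layout, ligand, seed=0)
    lig_idx = system.ligand_indices
    sc_idx = system.scaffold_indices
    displacements = np.arange(0.0, r_max + 0.5 * step, step)

    barriers: Dict[str, float] = {}
    for label, vec in directions.items():
        u = np.asarray(vec, dtype=float)
        u = u / np.linalg.norm(u)
        placed = place_ligand(system, "bound", orientation="tail_first", direction=u)
        chain0 = placed.positions[lig_idx]
        energies = np.empty(displacements.shape[0])
        for i, s in enumerate(displacements):
            pos = placed.positions.copy()
            pos[lig_idx] = chain0 + s * u[None, :]
            e_el, e_vdw = interaction_energy_positions(placed, pos, lig_idx, sc_idx)
            energies[i] = e_el + e_vdw
        barriers[label] = float(energies.max() - energies[0])
    return barriers
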