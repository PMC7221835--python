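"""Shared fixtures: small particle systems built programmatically."""

import numpy as np
import pytest

from ligandpath import (LigandSpec, ParticleSystem, ReceptorLayout,
                        build_funnel, build_system, widened_layout)


def make_system(positions, charges=None, eps=0.2, sigma=3.0, masses=40.0,
                bonds=(), bond_k=50.0, bond_r0=2.0, restrained=None,
                cutoff=12.0, switch_on=10.0, groups=None,
                container_radius=1.0e6, container_k=0.0, restraint_k=5.0):
    """Hand-rolled small system for force/integrator tests."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    as_arr = lambda v: np.full(n, float(v)) if np.isscalar(v) else np.asarray(v, float)
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    m = bonds.shape[0]
    bk = np.full(m, bond_k) if np.isscalar(bond_k) else np.asarray(bond_k, float)
    br = np.full(m, bond_r0) if np.isscalar(bond_r0) else np.asarray(bond_r0, float)
    if restrained is None:
        restrained = np.zeros(n, dtype=bool)
    if groups is None:
        groups = np.array(["free"] * n, dtype=object)
    return ParticleSystem(
        positions=pos,
        charges=as_arr(charges if charges is not None else 0.0),
        lj_epsilon=as_arr(eps), lj_sigma=as_arr(sigma), masses=as_arr(masses),
        bonds=bonds, bond_k=bk, bond_r0=br,
        restrained=np.asarray(restrained, bool),
        reference_positions=pos.copy(),
        groups=np.asarray(groups, dtype=object),
        restraint_k=restraint_k,
        container_radius=container_radius, container_k=container_k,
        cutoff=cutoff, switch_on=switch_on,
    )


@pytest.fixture(scope="session")
def widened():
    """The standard toy experiment: TM1–TM7 gate widened by 50%."""
    layout = widened_layout()
    ligand = LigandSpec()
    system = build_system(layout, ligand, seed=1)
    return layout, ligand, system


@pytest.fixture(scope="session")
def funnel():
    return build_funnel()


@pytest.fixture()
def free_pair():
    """Two neutral LJ beads 5 Å apart, no bonds or restraints."""
    return make_system([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]], cutoff=100.0,
                       switch_on=90.0)
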