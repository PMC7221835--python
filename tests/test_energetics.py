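"""Interaction-energy decomposition and profiles."""

import numpy as np
import pytest

from ligandpath import (LigandSpec, Trajectory, build_funnel, build_system,
                        compute_forces, energy_profile, initial_state,
                        interaction_energy, supervise, widened_layout)
from ligandpath.energetics import interaction_energy_positions
from ligandpath.sumd import SuMDConfig
from ligandpath.toy_receptor import place_ligand

from conftest import make_system


def two_group_system(seed=0, n_a=3, n_b=4):
    rng = np.random.default_rng(seed)
    pos_a = rng.uniform(0, 5, (n_a, 3))
    pos_b = rng.uniform(7, 12, (n_b, 3))
    pos = np.vstack([pos_a, pos_b])
    groups = ["A"] * n_a + ["B"] * n_b
    return make_system(pos, charges=rng.uniform(-0.5, 0.5, n_a + n_b),
                       eps=rng.uniform(0.1, 0.4, n_a + n_b),
                       sigma=rng.uniform(2.5, 3.4, n_a + n_b),
                       bonds=[(0, 1), (n_a, n_a + 1)], groups=groups,
                       cutoff=12.0, switch_on=10.0)


def test_distant_neutral_groups_have_zero_interaction():
    system = make_system([[0, 0, 0], [30.0, 0, 0]], groups=["A", "B"])
    assert interaction_energy(system, system.positions, "A", "B") == (0.0, 0.0)


def test_unit_charge_pair_at_ten_angstrom():
    system = make_system([[0, 0, 0], [10.0, 0, 0]], charges=[1.0, -1.0],
                         eps=0.0, groups=["A", "B"], cutoff=100.0,
                         switch_on=90.0)
    e_elec, e_vdw = interaction_energy(system, system.positions, "A", "B")
    assert e_elec == pytest.approx(-33.206, abs=5e-4)
    assert e_vdw == 0.0


def test_symmetric_in_group_order():
    system = two_group_system()
    ab = interaction_energy(system, system.positions, "A", "B")
    ba = interaction_energy(system, system.positions, "B", "A")
    assert ab == ba


def test_overlapping_groups_rejected():
    system = two_group_system()
    with pytest.raises(ValueError, match="disjoint"):
        interaction_energy(system, system.positions, "A", [0, 1, 3])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cross_check_against_whole_minus_parts(seed):
    """Pairwise interaction = full nonbonded energy minus each group alone."""
    system = two_group_system(seed)
    idx_a = system.group_indices("A")
    idx_b = system.group_indices("B")

    def nb_energy(sub_idx):
        sub_list = [int(i) for i in sub_idx]
        bonds = [(sub_list.index(i), sub_list.index(j))
                 for i, j in system.bonds if i in sub_list and j in sub_list]
        sub = make_system(
            system.positions[sub_list], charges=system.charges[sub_list],
            eps=system.lj_epsilon[sub_list], sigma=system.lj_sigma[sub_list],
            bonds=bonds, cutoff=system.cutoff, switch_on=system.switch_on)
        _, terms = compute_forces(sub)
        return terms.e_lj + terms.e_coulomb

    full_idx = np.arange(system.n_particles)
    cross = sum(interaction_energy(system, system.positions, idx_a, idx_b))
    assert cross == pytest.approx(
        nb_energy(full_idx) - nb_energy(idx_a) - nb_energy(idx_b), abs=1e-10)


def test_static_trajectory_gives_constant_profile():
    system = two_group_system()
    frames = np.repeat(system.positions[None], 5, axis=0)
    traj = Trajectory(np.arange(5.0), frames)
    prof = energy_profile(system, traj, "A", "B")
    assert np.ptp(prof.e_elec) == 0.0 and np.ptp(prof.e_vdw) == 0.0


def test_decomposition_identity_holds_at_every_sample():
    system = two_group_system(3)
    rng = np.random.default_rng(5)
    frames = system.positions[None] + rng.normal(0, 0.3, (20, system.n_particles, 3))
    prof = energy_profile(system, Trajectory(np.arange(20.0), frames), "A", "B")
    np.testing.assert_array_equal(prof.e_total, prof.e_elec + prof.e_vdw)


def test_frame_shape_mismatch_names_frame():
    system = two_group_system()
    frames = np.zeros((3, system.n_particles + 1, 3))
    with pytest.raises(ValueError, match="frame"):
        energy_profile(system, Trajectory(np.arange(3.0), frames), "A", "B")


def test_vdw_trend_decreases_during_funnel_capture():
    """As the ligand falls into the site, the smoothed vdW energy drops."""
    funnel = build_funnel()
    cfg = SuMDConfig(arrival_radius=4.0, slice_length=100, epsilon=0.1,
                     max_consecutive_rejects=200, max_total_steps=200_000,
                     dt=0.01, temperature=300.0, friction=5.0, base_seed=21)
    result = supervise(funnel, initial_state(funnel, 300.0, seed=21), cfg)
    assert result.termination == "arrived"
    prof = energy_profile(funnel, result.trajectory, funnel.ligand_indices,
                          funnel.group_indices("site"))
    sm = prof.smoothed(window=10)
    assert sm.e_vdw[-1] < sm.e_vdw[0] - 1.0
    assert np.polyfit(sm.time, sm.e_vdw, 1)[0] < 0


def test_like_charged_rim_repels_entering_head():
    """A charged head passing a like-charged gate rim sees positive
    electrostatic energy during the initial entry stage."""
    layout = widened_layout()
    ligand = LigandSpec()  # head charge -1
    system = build_system(layout, ligand, seed=0)
    rim = np.isin(system.groups, ["helix-1", "helix-7"])
    system.charges[rim] = -0.2  # same sign as the ligand head
    placed = place_ligand(system, "outside_gate", direction="TM1-TM7",
                          orientation="tail_first")
    u = layout.gate_unit_vector(layout.gate_index("TM1-TM7"))
    lig = placed.ligand_indices
    sc = placed.scaffold_indices
    chain0 = placed.positions[lig]
    e_elec_path = []
    for s in np.arange(0.0, 8.0, 0.5):  # move inward toward the gate
        pos = placed.positions.copy()
        pos[lig] = chain0 - s * u[None, :]
        e_el, _ = interaction_energy_positions(placed, pos, lig, sc)
        e_elec_path.append(e_el)
    assert max(e_elec_path) > 0.0
    assert e_elec_path[np.argmax(np.abs(e_elec_path))] > 0.0
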