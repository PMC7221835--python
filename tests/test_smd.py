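"""Steered pulling: pull-atom selection, spring math, record invariants."""

import numpy as np
import pytest

from ligandpath import (DirectionSpec, PullSchedule, initial_state, run_smd,
                        select_pull_atoms)
from ligandpath.units import KCAL_PER_MOL_ANG_TO_PN

from conftest import make_system


def chain_system(offsets, groups=None):
    """Ligand-only chain along x for selection tests."""
    n = len(offsets)
    if groups is None:
        groups = ["ligand-head"] + ["ligand-tail"] * (n - 1)
    return make_system([[x, y, 0.0] for x, y in offsets], eps=0.0,
                       groups=groups)


class TestSelectPullAtoms:
    def setup_method(self):
        self.chain = chain_system([(i * 2.0, 0.0) for i in range(5)])

    def test_plus_x_selects_leading_bead(self):
        idx = select_pull_atoms(self.chain, DirectionSpec("x", (1, 0, 0)), 1)
        assert list(idx) == [4]

    def test_minus_x_selects_opposite_terminal(self):
        idx = select_pull_atoms(self.chain, DirectionSpec("-x", (-1, 0, 0)), 1)
        assert list(idx) == [0]

    def test_diagonal_direction_on_l_shaped_ligand_matches_brute_force(self):
        offsets = [(0, 0), (2, 0), (4, 0), (4, 2), (4, 4)]
        system = chain_system(offsets)
        direction = DirectionSpec("diag", (1, 1, 0))
        idx = select_pull_atoms(system, direction, 1)
        pos = system.positions
        com = pos.mean(axis=0)
        proj = (pos - com) @ direction.vector
        assert list(idx) == [int(np.argmax(proj))]

    def test_ties_break_by_ascending_index(self):
        square = chain_system([(0, 0), (0, 2), (2, 0), (2, 2)])
        idx = select_pull_atoms(square, DirectionSpec("x", (1, 0, 0)), 1)
        assert list(idx) == [2]  # beads 2,3 tie on x; lower index wins

    def test_multi_atom_subset(self):
        idx = select_pull_atoms(self.chain, DirectionSpec("x", (1, 0, 0)), 2)
        assert list(idx) == [3, 4]

    def test_empty_ligand_rejected(self):
        bare = make_system([[0, 0, 0]], groups=["free"])
        with pytest.raises(ValueError):
            select_pull_atoms(bare, DirectionSpec("x", (1, 0, 0)), 1)


def test_direction_vectors_are_normalized():
    d = DirectionSpec("d", (3.0, 4.0, 0.0))
    assert np.linalg.norm(d.vector) == pytest.approx(1.0, abs=1e-12)


class TestRunSMD:
    def test_frozen_com_force_ramp_matches_k_v_t(self):
        """Immovable pulled bead: |F| = k·v·t; the published protocol's
        k = 70 pN/Å, v = 0.3 m/s gives 210 pN after 1 ns."""
        system = make_system([[0.0, 0.0, 0.0]], eps=0.0, masses=1.0e12,
                             groups=["ligand-head"])
        schedule = PullSchedule(k=70.0, v=0.3, duration=1000.0, record_every=100)
        state = initial_state(system, 0.0, seed=0)
        rec, _ = run_smd(system, state, DirectionSpec("x", (1, 0, 0)), schedule,
                         dt=0.1, temperature=0.0, friction=0.0)
        fmag = np.linalg.norm(rec.spring_force, axis=1)
        assert fmag[-1] == pytest.approx(210.0, abs=0.1)
        np.testing.assert_allclose(fmag, 70.0 * 0.003 * rec.time, atol=0.1)

    def test_zero_velocity_anchor_is_stationary_and_work_free(self):
        system = make_system([[0.0, 0.0, 0.0]], eps=0.0, masses=40.0,
                             groups=["ligand-head"])
        schedule = PullSchedule(k=70.0, v=0.0, duration=10.0, record_every=10)
        state = initial_state(system, 0.0, seed=0)
        rec, _ = run_smd(system, state, DirectionSpec("x", (1, 0, 0)), schedule,
                         dt=0.01, temperature=0.0, friction=0.0)
        assert np.ptp(rec.anchor, axis=0).max() == 0.0
        assert np.abs(rec.spring_force).max() < 1e-9

    def test_anchor_advances_exactly_at_constant_velocity(self, widened):
        _, _, system = widened
        direction = DirectionSpec("TM1-TM7",
                                  system.layout.gate_unit_vector(6))
        schedule = PullSchedule(v=15.0, duration=20.0, record_every=10)
        state = initial_state(system, 300.0, seed=4)
        rec, _ = run_smd(system, state, direction, schedule, dt=0.01)
        expected = rec.anchor[0] + schedule.v_ang_per_ps \
            * rec.time[:, None] * direction.vector
        np.testing.assert_allclose(rec.anchor, expected, atol=1e-9)

    def test_recorded_forces_replay_from_anchor_and_com(self, widened):
        """k·(anchor − COM) recomputed from the record matches the record."""
        _, _, system = widened
        direction = DirectionSpec("TM1-TM7", system.layout.gate_unit_vector(6))
        schedule = PullSchedule(v=15.0, duration=20.0, record_every=10)
        state = initial_state(system, 300.0, seed=4)
        rec, _ = run_smd(system, state, direction, schedule, dt=0.01)
        replayed = schedule.k_kcal * (rec.anchor - rec.pulled_com) \
            * KCAL_PER_MOL_ANG_TO_PN
        np.testing.assert_allclose(replayed, rec.spring_force, atol=1e-9)

    def test_record_length_matches_schedule(self, widened):
        _, _, system = widened
        direction = DirectionSpec("UP", (0, 0, 1))
        dt = 0.01
        schedule = PullSchedule(v=15.0, duration=13.0, record_every=7)
        state = initial_state(system, 300.0, seed=4)
        rec, _ = run_smd(system, state, direction, schedule, dt=dt)
        assert len(rec) == int(schedule.duration / (dt * schedule.record_every)) + 1

    def test_overdamped_free_ligand_reaches_drag_limited_force(self):
        """Steady pull of a free bead: spring force ≈ m·γ·v (fitted drag)."""
        m, gamma, v = 40.0, 20.0, 15.0 * 0.01
        system = make_system([[0.0, 0.0, 0.0]], eps=0.0, masses=m,
                             groups=["ligand-head"])
        schedule = PullSchedule(k=70.0, v=15.0, duration=50.0, record_every=10)
        state = initial_state(system, 0.0, seed=0)
        rec, _ = run_smd(system, state, DirectionSpec("x", (1, 0, 0)), schedule,
                         dt=0.005, temperature=0.0, friction=gamma)
        from ligandpath.units import KCAL_TO_AKMA
        expected_pn = m * gamma * v / KCAL_TO_AKMA * KCAL_PER_MOL_ANG_TO_PN
        tail = np.linalg.norm(rec.spring_force[-20:], axis=1).mean()
        assert tail == pytest.approx(expected_pn, rel=0.05)

    def test_escape_truncates_record_with_flag(self):
        system = make_system([[0.0, 0.0, 0.0]], eps=0.0, masses=40.0,
                             groups=["ligand-head"], container_radius=1e6,
                             container_k=0.0)
        system.container_radius = 5.0  # bounds check only; no wall force
        schedule = PullSchedule(k=700.0, v=50.0, duration=30.0, record_every=10)
        state = initial_state(system, 0.0, seed=0)
        rec, _ = run_smd(system, state, DirectionSpec("x", (1, 0, 0)), schedule,
                         dt=0.01, temperature=0.0, friction=1.0)
        assert rec.truncated
        assert np.linalg.norm(rec.pulled_com[-1]) <= 5.0
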