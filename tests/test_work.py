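"""Work integration, maximal force, aggregation, and pathway ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligandpath import (DirectionComparison, DirectionStats, ForceRecord,
                        WorkProfile, aggregate_direction, cumulative_work,
                        integrate_work, integrate_work_kcal, max_force,
                        rank_pathways, work_profile)
from ligandpath.units import KCAL_PER_MOL_ANG_TO_PN, work_kcal_to_pn_ang


def record_1d(x, fx, direction="D"):
    """Force record for motion along x with force fx(x), both arrays."""
    x = np.asarray(x, float)
    n = x.shape[0]
    com = np.zeros((n, 3))
    com[:, 0] = x
    force = np.zeros((n, 3))
    force[:, 0] = np.asarray(fx, float)
    return ForceRecord(time=np.arange(n, dtype=float), anchor=com.copy(),
                       pulled_com=com, spring_force=force, direction=direction)


class TestIntegrateWork:
    def test_constant_force_over_straight_line(self):
        rec = record_1d([0, 1, 2, 3, 4, 5], [10.0] * 6)
        assert integrate_work(rec) == pytest.approx(50.0, abs=1e-12)

    def test_zero_force_gives_zero_work(self):
        rec = record_1d(np.linspace(0, 5, 40), np.zeros(40))
        assert integrate_work(rec) == 0.0

    def test_trapezoid_exact_for_linear_force(self):
        x = np.arange(0.0, 5.0 + 1e-12, 0.01)
        rec = record_1d(x, 2.0 * x)
        assert integrate_work(rec) == pytest.approx(25.0, rel=1e-12)

    def test_matches_dense_quadrature_on_smooth_profile(self):
        g = lambda x: 12.0 + 5.0 * np.sin(1.3 * x) + 0.4 * x ** 2
        x_coarse = np.linspace(0.0, 10.0, 201)
        rec = record_1d(x_coarse, g(x_coarse))
        x_fine = np.linspace(0.0, 10.0, 200_001)
        oracle = np.trapezoid(g(x_fine), x_fine)
        assert integrate_work(rec) == pytest.approx(oracle, rel=1e-3)

    def test_full_vector_path_integral(self):
        # helical path with force along the tangent: W = |F| * arc length
        t = np.linspace(0, 2 * np.pi, 2001)
        com = np.stack([np.cos(t), np.sin(t), 0.1 * t], axis=1)
        tangent = np.stack([-np.sin(t), np.cos(t), 0.1 * np.ones_like(t)], axis=1)
        tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
        rec = ForceRecord(time=t, anchor=com, pulled_com=com,
                          spring_force=3.0 * tangent)
        arc = 2 * np.pi * np.sqrt(1 + 0.01)
        assert integrate_work(rec) == pytest.approx(3.0 * arc, rel=1e-4)

    def test_single_sample_and_nonmonotone_time_rejected(self):
        one = record_1d([0.0], [1.0])
        with pytest.raises(ValueError):
            integrate_work(one)
        bad = record_1d([0, 1, 2], [1, 1, 1])
        bad.time = np.array([0.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="increasing"):
            integrate_work(bad)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=1, max_value=98), st.integers(0, 2 ** 31 - 1))
    def test_path_additivity_at_any_split(self, split, seed):
        rng = np.random.default_rng(seed)
        n = 100
        com = np.cumsum(rng.normal(0, 0.3, (n, 3)), axis=0)
        force = rng.normal(0, 5.0, (n, 3))
        t = np.arange(n, dtype=float)
        whole = ForceRecord(time=t, anchor=com, pulled_com=com,
                            spring_force=force)
        a = ForceRecord(time=t[:split + 1], anchor=com[:split + 1],
                        pulled_com=com[:split + 1],
                        spring_force=force[:split + 1])
        b = ForceRecord(time=t[split:], anchor=com[split:],
                        pulled_com=com[split:], spring_force=force[split:])
        total = integrate_work(whole)
        assert integrate_work(a) + integrate_work(b) == pytest.approx(
            total, rel=1e-12, abs=1e-9)

    def test_unit_round_trip_identity(self):
        rec = record_1d([0, 2, 4], [7.0, 7.0, 7.0])
        w_pn_ang = integrate_work(rec)
        assert work_kcal_to_pn_ang(integrate_work_kcal(rec)) == pytest.approx(
            w_pn_ang, rel=1e-14)
        assert KCAL_PER_MOL_ANG_TO_PN == pytest.approx(69.479)


class TestMaxForce:
    def test_vector_magnitude(self):
        rec = record_1d([0, 1], [0, 0])
        rec.spring_force = np.array([[3.0, 4.0, 0.0], [1.0, 0.0, 0.0]])
        assert max_force(rec) == pytest.approx(5.0)

    def test_all_zero_record(self):
        rec = record_1d([0, 1, 2], [0, 0, 0])
        assert max_force(rec) == 0.0

    def test_monotone_ramp_peaks_at_last_sample(self):
        fx = np.linspace(0, 9, 10)
        rec = record_1d(np.linspace(0, 5, 10), fx)
        assert max_force(rec) == pytest.approx(9.0)


def profile_with(direction, works_kcal, fmax=None):
    prof = WorkProfile(direction)
    prof.works_pn_ang = [work_kcal_to_pn_ang(w) for w in works_kcal]
    prof.max_forces_pn = list(fmax if fmax is not None else works_kcal)
    return prof


class TestAggregate:
    def test_mean_and_sample_sd(self):
        stats = aggregate_direction([profile_with("A", [10.0, 20.0, 30.0])])
        assert stats.mean_work_kcal == pytest.approx(20.0)
        assert stats.sd_work_kcal == pytest.approx(10.0)
        assert not stats.sd_degenerate

    def test_single_repeat_flags_degenerate_sd(self):
        stats = aggregate_direction([profile_with("A", [12.0])])
        assert stats.mean_work_kcal == pytest.approx(12.0)
        assert stats.sd_work_kcal == 0.0
        assert stats.sd_degenerate

    def test_repeat_order_invariance(self):
        a = aggregate_direction([profile_with("A", [1.0, 5.0, 9.0])])
        b = aggregate_direction([profile_with("A", [9.0, 1.0, 5.0])])
        assert a == b

    def test_mixed_labels_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate_direction([profile_with("A", [1.0]),
                                 profile_with("B", [2.0])])

    def test_work_profile_rejects_mislabelled_record(self):
        rec = record_1d([0, 1], [1, 1], direction="B")
        with pytest.raises(ValueError):
            work_profile("A", [rec])


def stats(direction, mean_w, sd_w, mean_f):
    return DirectionStats(direction, 3, mean_w, sd_w, mean_f, 0.0, False)


class TestRankPathways:
    def test_plain_ordering_by_mean_work(self):
        comp = DirectionComparison([stats("C", 30, 1, 5), stats("A", 10, 1, 5),
                                    stats("B", 20, 1, 5)])
        order, verdict = rank_pathways(comp)
        assert order == ["A", "B", "C"]
        assert verdict["winner"] == "A"
        assert not verdict["equivalent_pair"]

    def test_equivalent_pair_breaks_tie_by_max_force(self):
        comp = DirectionComparison([stats("A", 10.0, 3.0, 50.0),
                                    stats("B", 11.0, 3.0, 20.0),
                                    stats("C", 30.0, 1.0, 90.0)])
        order, verdict = rank_pathways(comp)
        assert order == ["B", "A", "C"]  # within SD; B has smaller max force
        assert verdict["equivalent_pair"]

    def test_needs_at_least_two_directions(self):
        with pytest.raises(ValueError):
            rank_pathways(DirectionComparison([stats("A", 1, 0, 1)]))

    def test_cumulative_work_is_running_trapezoid(self):
        x = np.linspace(0, 4, 5)
        rec = record_1d(x, 2.0 * x)
        cum = cumulative_work(rec)
        assert cum[0] == 0.0
        assert cum[-1] == pytest.approx(integrate_work(rec))
        assert np.all(np.diff(cum) >= 0)
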