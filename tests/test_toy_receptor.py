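"""Synthetic receptor builder: geometry, placement, ground-truth barriers."""

import dataclasses

import numpy as np
import pytest

from ligandpath import (BuildError, LigandSpec, ReceptorLayout, build_funnel,
                        build_system, ground_truth_barriers, place_ligand,
                        widened_layout)


@pytest.fixture(scope="module")
def symmetric():
    layout = ReceptorLayout()
    ligand = LigandSpec()
    return layout, ligand, build_system(layout, ligand, seed=1)


class TestLayoutValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_helices=2, gap_widths=(1.0, 1.0)),
        dict(gap_widths=(1.0,) * 6),
        dict(gap_widths=(1.0, 1.0, 1.0, -0.5, 1.0, 1.0, 1.0)),
        dict(pocket_radius=9.0),
        dict(widest_gate=0),  # gate 0 does not have the largest gap
        dict(gap_widths=(1.0,) * 6 + (2.0,), widest_gate=9),
    ])
    def test_invalid_layouts_rejected(self, kwargs):
        base = dict(gap_widths=kwargs.pop("gap_widths", (2.0,) * 7))
        if "widest_gate" in kwargs and kwargs["widest_gate"] == 0:
            base["gap_widths"] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            ReceptorLayout(**{**base, **kwargs})

    def test_gate_labels_wrap_around_the_ring(self):
        layout = ReceptorLayout()
        assert layout.gate_labels() == ("TM1-TM2", "TM2-TM3", "TM3-TM4",
                                        "TM4-TM5", "TM5-TM6", "TM6-TM7",
                                        "TM1-TM7")

    def test_widening_one_gate_widens_its_realized_arc(self):
        base = ReceptorLayout()
        wide = widened_layout(base)
        i = wide.widest_gate
        assert wide.realized_gap_widths()[i] > base.realized_gap_widths()[i]
        assert np.argmax(wide.realized_gap_widths()) == i


class TestBuildSystem:
    def test_deterministic_for_fixed_seed(self, symmetric):
        layout, ligand, system = symmetric
        again = build_system(layout, ligand, seed=1)
        np.testing.assert_array_equal(system.positions, again.positions)

    def test_particle_counts_and_groups_partition(self, symmetric):
        layout, ligand, system = symmetric
        labels = set(system.groups)
        assert {"membrane", "plug", "ligand-head", "ligand-tail"} <= labels
        assert sum(g.startswith("helix-") for g in labels) == layout.n_helices
        assert (system.ligand_indices.size == ligand.n_beads)
        # every particle has exactly one label; ligand is exactly the free set
        assert np.array_equal(system.restrained, ~np.isin(
            system.groups, ["ligand-head", "ligand-tail"]))

    def test_no_pair_closer_than_half_min_sigma(self, symmetric):
        _, _, system = symmetric
        d = np.linalg.norm(system.positions[:, None] - system.positions[None, :],
                           axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.5 * system.lj_sigma.min()

    def test_plug_absent_when_disabled(self):
        layout = ReceptorLayout(up_plug=False)
        system = build_system(layout, LigandSpec(), seed=0)
        assert "plug" not in set(system.groups)


class TestPlaceLigand:
    def test_bound_site_puts_com_in_pocket(self, symmetric):
        layout, ligand, system = symmetric
        placed = place_ligand(system, "bound")
        lig = placed.ligand_indices
        com = np.average(placed.positions[lig], axis=0,
                         weights=placed.masses[lig])
        assert np.linalg.norm(com - layout.pocket_center) <= layout.pocket_radius

    def test_outside_gate_tail_first_leads_with_tail(self, symmetric):
        layout, _, system = symmetric
        placed = place_ligand(system, "outside_gate", direction="TM1-TM7",
                              orientation="tail_first")
        gate_pt = layout.gate_unit_vector(layout.gate_index("TM1-TM7")) \
            * layout.helix_radius
        lig = placed.ligand_indices
        head = placed.positions[lig[0]]
        tail_end = placed.positions[lig[-1]]
        assert np.linalg.norm(tail_end - gate_pt) < np.linalg.norm(head - gate_pt)

    def test_head_first_is_chain_reversal_about_the_axis(self, symmetric):
        _, _, system = symmetric
        tail = place_ligand(system, "outside_gate", direction="TM1-TM7",
                            orientation="tail_first")
        head = place_ligand(system, "outside_gate", direction="TM1-TM7",
                            orientation="head_first")
        lig = system.ligand_indices
        np.testing.assert_allclose(head.positions[lig],
                                   tail.positions[lig][::-1], atol=1e-12)

    def test_unplaceable_site_raises_naming_site(self, symmetric):
        _, _, system = symmetric
        blocked = system.copy()
        blocked.lj_sigma[:] = 60.0  # clash floor grows beyond any placement
        with pytest.raises(BuildError, match="bound"):
            place_ligand(blocked, "bound")


class TestGroundTruthBarriers:
    def test_point_ligand_without_interactions_sees_no_barriers(self):
        layout = ReceptorLayout()
        ghost = LigandSpec(head_charge=0.0, head_epsilon=0.0,
                           tail_bead_epsilon=0.0)
        barriers = ground_truth_barriers(layout, ghost)
        assert all(abs(b) < 1e-12 for b in barriers.values())

    def test_symmetric_layout_has_equal_lateral_barriers(self, symmetric):
        layout, ligand, _ = symmetric
        barriers = ground_truth_barriers(layout, ligand)
        lateral = [v for k, v in barriers.items() if k != "UP"]
        assert max(lateral) / min(lateral) <= 1.01

    def test_widened_gate_is_the_lowest_barrier(self, widened):
        layout, ligand, _ = widened
        barriers = ground_truth_barriers(layout, ligand)
        assert min(barriers, key=barriers.get) == "TM1-TM7"

    def test_up_exit_blocked_by_plug(self, widened):
        layout, ligand, _ = widened
        barriers = ground_truth_barriers(layout, ligand)
        lateral = [v for k, v in barriers.items() if k != "UP"]
        assert barriers["UP"] > 10 * max(lateral)

    @pytest.mark.parametrize("factor", [1.2, 1.5, 2.0])
    def test_widening_never_raises_the_gate_barrier(self, factor):
        ligand = LigandSpec()
        base = ReceptorLayout()
        narrow = ground_truth_barriers(base, ligand)["TM1-TM7"]
        wide = ground_truth_barriers(widened_layout(base, factor=factor),
                                     ligand)["TM1-TM7"]
        assert wide <= narrow + 1e-9

    def test_gap_permutation_permutes_barriers(self):
        """Rotating the widened gap around the ring moves the minimum with it.

        The rotated geometries differ slightly (membrane/plug bead rings
        are laid out from a fixed phase), so barrier equality holds to the
        bead-discretization level, ~0.5%.
        """
        ligand = LigandSpec()
        gaps = [2.0] * 7
        gaps[6] = 3.0
        b1 = ground_truth_barriers(
            ReceptorLayout(gap_widths=tuple(gaps), widest_gate=6), ligand)
        gaps2 = [2.0] * 7
        gaps2[3] = 3.0
        b2 = ground_truth_barriers(
            ReceptorLayout(gap_widths=tuple(gaps2), widest_gate=3), ligand)
        assert min(b1, key=b1.get) == "TM1-TM7"
        assert min(b2, key=b2.get) == "TM4-TM5"
        assert b1["TM1-TM7"] == pytest.approx(b2["TM4-TM5"], rel=5e-3)


class TestFunnel:
    def test_funnel_structure(self, funnel):
        assert set(funnel.groups) == {"site", "ligand-head", "ligand-tail"}
        assert funnel.restrained[funnel.group_indices("site")].all()
        assert not funnel.restrained[funnel.ligand_indices].any()

    def test_ligand_starts_at_requested_distance(self):
        sys_ = build_funnel(start_distance=15.0)
        lig = sys_.ligand_indices
        com = np.average(sys_.positions[lig], axis=0, weights=sys_.masses[lig])
        assert np.linalg.norm(com) == pytest.approx(15.0, abs=1e-9)
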