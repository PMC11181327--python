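import numpy as np
import pytest

from resinmap import contacts
from resinmap.contacts import (
    ContactCounts,
    OccupancyProfile,
    convergence_series,
    frame_contacts,
    headgroup_center,
    interaction_counts,
    interaction_surface,
    occupancy_profile,
    relative_occupancy,
    residue_min_distance,
    residue_sasa,
    surface_sasa,
)
from resinmap.io import Atom, SelectionSpec, Structure
from resinmap.synthetic import simulate_two_state

from conftest import brute_force_counts, random_geometry_trajectory


class TestHeadgroupCenter:
    def test_single_atom(self, tripeptide):
        sel = SelectionSpec(name="one", atom_ids=(7,))
        np.testing.assert_allclose(
            headgroup_center(tripeptide.coords, tripeptide, sel), [5.0, 5.0, 0.0]
        )

    def test_equal_masses_midpoint(self):
        atoms = [Atom(1, "C1", "C", 1, "LIG", "L"), Atom(2, "C2", "C", 1, "LIG", "L")]
        st = Structure(atoms, np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                       ligand_resnames=frozenset({"LIG"}))
        sel = SelectionSpec(name="lig", res_name="LIG")
        np.testing.assert_allclose(headgroup_center(st.coords, st, sel), [1.0, 0, 0])

    def test_carbon_oxygen_mass_weighting(self, tripeptide, headgroup):
        # C at x=5.0, O at x=6.6: centre at 5.0 + 1.6·mO/(mC+mO)
        expected_x = 5.0 + 1.6 * 15.999 / (12.011 + 15.999)
        c = headgroup_center(tripeptide.coords, tripeptide, headgroup)
        assert c[0] == pytest.approx(expected_x, abs=1e-12)

    def test_empty_selection_errors(self, tripeptide):
        sel = SelectionSpec(name="none", res_name="TRP")
        with pytest.raises(Exception, match="zero atoms"):
            headgroup_center(tripeptide.coords, tripeptide, sel)


class TestMinimumImageDistance:
    def test_plain_distance(self, tripeptide):
        d = residue_min_distance(
            np.array([3.9, 0, 0]), tripeptide.coords, tripeptide, ("A", 2),
            np.array([100.0, 100, 100]),
        )
        assert d == pytest.approx(6.1)

    def test_wraps_across_box(self, tripeptide):
        d = residue_min_distance(
            np.array([-0.5, 0, 0]), tripeptide.coords, tripeptide, ("A", 1),
            np.array([10.0, 10, 10]),
        )
        assert d == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_27_image_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([12.0, 15.0, 9.0])
        pts = rng.uniform(-5, 20, size=(20, 3))
        point = rng.uniform(-5, 20, size=3)
        fast = contacts.minimum_image_distances(point, pts, box)
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        )
        # wrap the separation into the primary cell first: enumeration over
        # neighbour images is exhaustive only for in-cell separations
        delta = pts - point
        delta -= box * np.floor(delta / box)
        brute = np.min(
            np.linalg.norm(delta[:, None, :] + shifts[None] * box, axis=-1), axis=1
        )
        np.testing.assert_allclose(fast, brute, atol=1e-10)


class TestFrameContacts:
    def _one_residue_at(self, x):
        atoms = [
            Atom(1, "CA", "C", 1, "ALA", "A"),
            Atom(2, "C1", "C", 2, "LIG", "L"),
        ]
        coords = np.array([[x, 0.0, 0.0], [0.0, 0.0, 0.0]])
        return Structure(atoms, coords, ligand_resnames=frozenset({"LIG"}))

    def test_strictly_inside_cutoff_included(self):
        st = self._one_residue_at(3.99)
        sel = SelectionSpec(name="hg", res_name="LIG")
        hits = frame_contacts(st.coords, st, sel, np.array([100.0] * 3))
        assert hits == {("A", 1)}

    def test_exactly_at_cutoff_excluded(self):
        st = self._one_residue_at(4.00)
        sel = SelectionSpec(name="hg", res_name="LIG")
        hits = frame_contacts(st.coords, st, sel, np.array([100.0] * 3))
        assert hits == set()

    def test_matches_brute_force_on_random_frame(self):
        traj, sel = random_geometry_trajectory(n_frames=1, n_residues=3, seed=9)
        hits = frame_contacts(traj.coords[0], traj.structure, sel, traj.box[0])
        oracle = brute_force_counts(traj, sel)
        assert hits == {r for r, c in oracle.items() if c == 1}


class TestInteractionCounts:
    def test_recovers_constructed_counts(self, small_run):
        traj, truth, headgroup = small_run
        counts = interaction_counts(traj, headgroup)
        for res in truth.columns:
            assert counts.counts[res] == int(truth[res].sum())

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_brute_force_oracle(self, seed):
        traj, sel = random_geometry_trajectory(n_frames=40, n_residues=8, seed=seed)
        counts = interaction_counts(traj, sel)
        assert counts.counts == brute_force_counts(traj, sel)

    def test_two_copies_indicator_vs_summed(self, small_run):
        traj, truth, _ = small_run
        # two identical headgroup selections = two co-located ligand copies
        copy1 = SelectionSpec(name="c1", res_name="LIG")
        copy2 = SelectionSpec(name="c2", atom_ids=(traj.structure.atoms[-1].atom_id,))
        ind = interaction_counts(traj, [copy1, copy2], mode="indicator")
        summed = interaction_counts(traj, [copy1, copy2], mode="summed")
        for res, c in ind.counts.items():
            assert summed.counts[res] == 2 * c  # both copies always hit together
            assert c <= ind.n_frames

    def test_zero_frames_rejected(self, small_run):
        traj, _, headgroup = small_run
        import dataclasses

        with pytest.raises(Exception):
            bad = dataclasses.replace(traj, coords=traj.coords[:0], box=traj.box[:0])
            interaction_counts(bad, headgroup)


class TestOccupancy:
    @pytest.mark.parametrize("count,expected", [(50, 0.25), (0, 0.0), (200, 1.0)])
    def test_fraction_of_frames(self, count, expected):
        cc = ContactCounts(counts={("A", 5): count}, n_frames=200)
        assert occupancy_profile(cc).occupancy[("A", 5)] == expected

    def test_invariant_under_frame_reordering(self, small_run):
        traj, _, headgroup = small_run
        import dataclasses

        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        shuffled = dataclasses.replace(
            traj, coords=traj.coords[perm], box=traj.box[perm]
        )
        a = occupancy_profile(interaction_counts(traj, headgroup))
        b = occupancy_profile(interaction_counts(shuffled, headgroup))
        assert a.occupancy == b.occupancy

    def test_relative_occupancy(self):
        prof = OccupancyProfile({("A", 1): 0.4, ("A", 2): 0.2}, n_frames=10)
        rel = relative_occupancy(prof)
        assert rel == {("A", 1): 1.0, ("A", 2): 0.5}
        single = OccupancyProfile({("A", 1): 0.123}, n_frames=10)
        assert relative_occupancy(single) == {("A", 1): 1.0}
        with pytest.raises(ValueError):
            relative_occupancy(OccupancyProfile({("A", 1): 0.0}, n_frames=10))


class TestInteractionSurface:
    @pytest.mark.parametrize(
        "f,included", [(0.051, True), (0.050, False), (0.049, False)]
    )
    def test_strict_threshold(self, f, included):
        prof = OccupancyProfile({("A", 1): f}, n_frames=1000)
        surf = interaction_surface(prof, 0.05)
        assert (("A", 1) in surf.members) is included

    def test_all_below_gives_empty_surface(self):
        prof = OccupancyProfile({("A", 1): 0.01, ("A", 2): 0.05}, n_frames=100)
        surf = interaction_surface(prof, 0.05)
        assert surf.n_residues == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        prof = OccupancyProfile(
            {("A", i): float(f) for i, f in enumerate(rng.random(30))}, n_frames=100
        )
        prev = set(interaction_surface(prof, 0.0).members)
        for thr in (0.1, 0.3, 0.5, 0.8):
            cur = set(interaction_surface(prof, thr).members)
            assert cur <= prev
            prev = cur


class TestConvergence:
    def test_all_ones(self):
        cs = convergence_series(np.ones(100), n_blocks=5)
        np.testing.assert_array_equal(cs.cumulative, 1.0)
        assert cs.block_sem == 0.0
        assert cs.final_value == 1.0

    def test_alternating_tends_to_half(self):
        x = np.tile([0, 1], 5000)
        cs = convergence_series(x, n_blocks=10)
        assert cs.final_value == pytest.approx(0.5, abs=1e-4)

    def test_cumulative_ends_at_mean(self):
        x = simulate_two_state(0.3, 5.0, 2000, seed=4).astype(float)
        cs = convergence_series(x, n_blocks=8)
        assert cs.final_value == pytest.approx(x.mean(), abs=1e-12)

    def test_block_sem_matches_replicate_sem(self):
        """The block standard error must estimate the true SE of the
        trajectory mean: compare the block SEM (averaged over 5 series to
        tame its own sampling noise) against the SD of the mean over 200
        independent replicate simulations of the same process."""
        p, tau, n = 0.3, 10.0, 20000
        sems = [
            convergence_series(
                simulate_two_state(p, tau, n, seed=1000 + i).astype(float), n_blocks=20
            ).block_sem
            for i in range(5)
        ]
        block_sem = np.mean(sems)
        means = [
            simulate_two_state(p, tau, n, seed=5000 + i).mean() for i in range(200)
        ]
        replicate_sem = np.std(means, ddof=1)
        assert abs(block_sem - replicate_sem) / replicate_sem < 0.30

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            convergence_series(np.ones(3), n_blocks=5)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        st = Structure(
            [Atom(1, "SE1", "SE", 1, "MET", "A")], np.zeros((1, 3))
        )
        area = residue_sasa(st, probe=1.4, n_points=960)[("A", 1)]
        expected = 4 * np.pi * (1.9 + 1.4) ** 2
        assert abs(area - expected) / expected < 0.02

    def test_enclosed_atom_has_zero_area(self):
        # central carbon caged by a dense shell of neighbours
        rng = np.random.default_rng(0)
        n_shell = 60
        pts = rng.standard_normal((n_shell, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        # golden-spiral-ish shell at 2.0 Å: every probe position is blocked
        phi = np.arccos(1 - 2 * (np.arange(n_shell) + 0.5) / n_shell)
        theta = np.pi * (1 + 5**0.5) * (np.arange(n_shell) + 0.5)
        shell = 2.0 * np.column_stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
        )
        atoms = [Atom(1, "C0", "C", 1, "ALA", "A")] + [
            Atom(i + 2, f"C{i+1}", "C", 2, "GLY", "A") for i in range(n_shell)
        ]
        st = Structure(atoms, np.vstack([[0, 0, 0], shell]))
        per_res = residue_sasa(st)
        assert per_res[("A", 1)] == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_atoms_additive(self):
        atoms = [Atom(1, "C1", "C", 1, "ALA", "A"), Atom(2, "C1", "C", 2, "GLY", "A")]
        st = Structure(atoms, np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        per_res = residue_sasa(st)
        sphere = 4 * np.pi * (1.7 + 1.4) ** 2
        assert per_res[("A", 1)] == pytest.approx(sphere, rel=0.02)
        assert per_res[("A", 2)] == pytest.approx(sphere, rel=0.02)

    def test_surface_sasa_requires_known_residues(self, tripeptide):
        from resinmap.contacts import InteractionSurface

        surf = InteractionSurface(members={("B", 99): 0.5}, threshold=0.05)
        with pytest.raises(ValueError, match="absent"):
            surface_sasa(tripeptide, surf)

    def test_surface_sasa_sums_member_residues(self, tripeptide):
        from resinmap.contacts import InteractionSurface

        per_res = residue_sasa(tripeptide)
        surf = InteractionSurface(
            members={("A", 1): 0.3, ("A", 3): 0.1}, threshold=0.05
        )
        total = surface_sasa(tripeptide, surf)
        assert total == pytest.approx(per_res[("A", 1)] + per_res[("A", 3)], rel=1e-6)
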