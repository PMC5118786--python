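import numpy as np
import pytest

from pepmem.core import Atom, Frame, Topology, Trajectory
from pepmem.membrane import (
    MembraneError,
    OrderParameterProfile,
    area_per_lipid,
    assign_leaflets,
    compare_order_groups,
    membrane_thickness,
    phosphate_plane_z,
    proximal_lipids,
    residue_depths,
    scd_of_vectors,
    scd_profile,
)
from pepmem.synthetic import (
    BilayerRecipe,
    Schedules,
    build_bilayer,
    build_ideal_peptide,
    evolve_trajectory,
    place_peptides,
)

from oracles import brute_force_proximal_lipids


def minimal_bilayer_frame(z_upper=17.5, z_lower=-17.5, n_per_leaflet=4,
                          box=(40.0, 40.0, 80.0)):
    """Headgroup-only bilayer: one P atom per lipid."""
    atoms, coords = [], []
    mol = 0
    for z in (z_upper, z_lower):
        for k in range(n_per_leaflet):
            atoms.append(Atom("P", "P", 1, "POPE", mol, "lipid"))
            coords.append([5.0 + 10.0 * k, 5.0, z + 40.0])
            mol += 1
    top = Topology(atoms, lipid_types={m: "POPE" for m in range(mol)})
    return Frame(np.array(coords), np.array(box)), top


class TestLeafletsAndPlanes:
    def test_even_split_by_construction(self, small_bilayer):
        asg = assign_leaflets(small_bilayer.frame(), small_bilayer.topology)
        assert len(asg.lipids("upper")) == len(asg.lipids("lower")) == 16

    def test_translation_equivariance(self, small_bilayer):
        frame = small_bilayer.frame()
        asg0 = assign_leaflets(frame, small_bilayer.topology)
        shifted = Frame(frame.coordinates + [3.0, -7.0, 12.0], frame.box)
        asg1 = assign_leaflets(shifted, small_bilayer.topology)
        assert asg0.leaflet == asg1.leaflet
        assert asg1.midplane_z == pytest.approx(asg0.midplane_z + 12.0)

    def test_midplane_tie_goes_upper_with_warning(self):
        frame, top = minimal_bilayer_frame(z_upper=10.0, z_lower=-10.0, n_per_leaflet=1)
        # add one P exactly on the midplane
        atoms = list(top.atoms) + [Atom("P", "P", 1, "POPE", 2, "lipid")]
        top2 = Topology(atoms, lipid_types={0: "POPE", 1: "POPE", 2: "POPE"})
        coords = np.vstack([frame.coordinates, [[20.0, 20.0, 40.0]]])
        with pytest.warns(UserWarning, match="midplane"):
            asg = assign_leaflets(Frame(coords, frame.box), top2)
        assert asg.leaflet[2] == "upper"

    def test_phosphate_plane_is_leaflet_mean(self):
        frame, top = minimal_bilayer_frame(z_upper=17.5, z_lower=-17.5)
        asg = assign_leaflets(frame, top)
        assert phosphate_plane_z(frame, top, asg, "upper") == pytest.approx(57.5)
        frame.coordinates[0, 2] = 55.0
        frame.coordinates[1, 2] = 60.0
        frame.coordinates[2, 2] = 55.0
        frame.coordinates[3, 2] = 60.0
        assert phosphate_plane_z(frame, top, asg, "upper") == pytest.approx(57.5)

    def test_noisy_plane_recovers_mean_within_standard_error(self):
        rng = np.random.default_rng(0)
        n = 256
        atoms = [Atom("P", "P", 1, "POPE", m, "lipid") for m in range(n)]
        top = Topology(atoms, lipid_types={m: "POPE" for m in range(n)})
        z = rng.normal(17.5, 1.0, n)
        coords = np.column_stack([rng.uniform(0, 100, n), rng.uniform(0, 100, n), z])
        frame = Frame(coords, np.array([100.0, 100.0, 100.0]))
        asg = assign_leaflets(frame, top)
        # single leaflet situation: force all upper
        for m in asg.leaflet:
            asg.leaflet[m] = "upper"
        assert phosphate_plane_z(frame, top, asg, "upper") == pytest.approx(
            z.mean(), abs=1e-12)
        assert abs(z.mean() - 17.5) < 3.0 / np.sqrt(n)


class TestGeometry:
    def test_area_per_lipid_of_study_patch(self):
        frame, _top = minimal_bilayer_frame(box=(120.0, 120.0, 100.0))
        assert area_per_lipid(frame, 256) == pytest.approx(56.25)

    def test_area_scales_with_box(self):
        frame, _top = minimal_bilayer_frame(box=(120.0, 120.0, 100.0))
        double = Frame(frame.coordinates, np.array([240.0, 120.0, 100.0]))
        assert area_per_lipid(double, 256) == pytest.approx(2 * area_per_lipid(frame, 256))

    def test_zero_leaflet_count_error(self):
        frame, _top = minimal_bilayer_frame()
        with pytest.raises(MembraneError):
            area_per_lipid(frame, 0)

    @pytest.mark.parametrize("zu,zl,expected", [(17.5, -17.5, 35.0), (10.0, -10.0, 20.0)])
    def test_thickness_from_plane_separation(self, zu, zl, expected):
        frame, top = minimal_bilayer_frame(z_upper=zu, z_lower=zl)
        assert membrane_thickness(frame, top) == pytest.approx(expected)

    def test_swapped_leaflet_labels_error(self):
        frame, top = minimal_bilayer_frame()
        asg = assign_leaflets(frame, top)
        swapped = {m: ("upper" if s == "lower" else "lower")
                   for m, s in asg.leaflet.items()}
        asg.leaflet.update(swapped)
        with pytest.raises(MembraneError, match="swapped"):
            membrane_thickness(frame, top, asg)

    def test_geometry_translation_equivariance(self, small_bilayer):
        frame = small_bilayer.frame()
        top = small_bilayer.topology
        t0 = membrane_thickness(frame, top)
        a0 = area_per_lipid(frame, 16)
        moved = Frame(frame.coordinates + [11.0, -4.0, 9.0], frame.box)
        assert membrane_thickness(moved, top) == pytest.approx(t0, abs=1e-9)
        assert area_per_lipid(moved, 16) == pytest.approx(a0)


class TestResidueDepths:
    def test_initial_placement_depth_is_20(self, bilayer_with_peptides):
        traj = Trajectory(bilayer_with_peptides.topology,
                          [bilayer_with_peptides.frame()])
        for pep in bilayer_with_peptides.peptides:
            prof = residue_depths(traj, pep.molecule_id)
            assert prof.depth[0].mean() == pytest.approx(20.0, abs=2.0)
            assert np.all(prof.depth[0] > 10.0)

    def test_linear_insertion_schedule_recovered(self, small_bilayer):
        system = place_peptides(small_bilayer, [build_ideal_peptide("AAAA")],
                                height=20.0, seed=1)
        pid = system.peptides[0].molecule_id
        traj = evolve_trajectory(system, 6, noise_sd=0.0,
                                 schedules=Schedules(insertion={pid: (0.0, -25.0)}),
                                 seed=2)
        prof = residue_depths(traj, pid)
        mean_depth = prof.depth.mean(axis=1)
        np.testing.assert_allclose(mean_depth, np.linspace(20.0, -5.0, 6), atol=0.75)

    def test_residue_on_plane_has_zero_depth(self, small_bilayer):
        system = place_peptides(small_bilayer, [build_ideal_peptide("AA")],
                                height=0.0, seed=3)
        traj = Trajectory(system.topology, [system.frame()])
        prof = residue_depths(traj, system.peptides[0].molecule_id)
        assert abs(prof.depth[0].mean()) < 2.5

    def test_depth_z_translation_equivariance(self, bilayer_with_peptides):
        frame = bilayer_with_peptides.frame()
        top = bilayer_with_peptides.topology
        pid = bilayer_with_peptides.peptides[0].molecule_id
        d0 = residue_depths(Trajectory(top, [frame]), pid).depth
        moved = Frame(frame.coordinates + [0.0, 0.0, 13.0], frame.box)
        d1 = residue_depths(Trajectory(top, [moved]), pid).depth
        np.testing.assert_allclose(d1, d0, atol=1e-9)


class TestOrderParameters:
    def test_all_trans_chains_give_half_magnitude(self):
        system = build_bilayer(BilayerRecipe(nx=2, ny=2, order_magnitude=0.5), seed=0)
        prof = scd_profile(system.trajectory(), window_ps=(0.0, 0.0))
        np.testing.assert_allclose(prof.scd_signed, -0.5, atol=1e-12)
        np.testing.assert_allclose(prof.scd_magnitude, 0.5, atol=1e-12)

    def test_isotropic_vectors_average_to_zero(self):
        rng = np.random.default_rng(12)
        v = rng.normal(size=(100_000, 3))
        assert abs(scd_of_vectors(v).mean()) < 0.01

    def test_magic_angle_is_exactly_zero(self):
        v = np.array([[np.sqrt(2.0 / 3.0), 0.0, np.sqrt(1.0 / 3.0)]])
        assert scd_of_vectors(v)[0] == pytest.approx(0.0, abs=1e-12)

    def test_sample_values_bounded(self):
        rng = np.random.default_rng(3)
        s = scd_of_vectors(rng.normal(size=(5000, 3)))
        assert s.min() >= -0.5 - 1e-12 and s.max() <= 1.0 + 1e-12

    def test_target_order_recovered_within_002(self):
        # 8x8 leaflets x 2 H x 8 frames -> >2000 C-H samples per carbon
        system = build_bilayer(BilayerRecipe(nx=8, ny=8, order_magnitude=0.18), seed=5)
        traj = evolve_trajectory(system, 8, noise_sd=0.0, seed=6)
        prof = scd_profile(traj, window_ps=(0.0, traj.times[-1]))
        assert np.all(prof.n_samples >= 2000)
        np.testing.assert_allclose(prof.scd_magnitude, 0.18, atol=0.02)

    def test_proximal_group_matches_brute_force_oracle(self, bilayer_with_peptides):
        frame = bilayer_with_peptides.frame()
        top = bilayer_with_peptides.topology
        # drop one peptide onto the headgroups so some lipids qualify
        pep = bilayer_with_peptides.peptides[0]
        frame.coordinates[pep.atom_start:pep.atom_stop, 2] -= 19.0
        for cutoff in (4.0, 8.0):
            assert proximal_lipids(frame, top, cutoff) == \
                brute_force_proximal_lipids(frame, top, cutoff)

    def test_window_outside_trajectory_error(self, small_bilayer):
        with pytest.raises(MembraneError, match="window"):
            scd_profile(small_bilayer.trajectory(), window_ps=(100.0, 200.0))

    def test_per_lipid_type_profiles_partition_samples(self, small_bilayer):
        traj = small_bilayer.trajectory()
        full = scd_profile(traj, window_ps=(0.0, 0.0))
        pope = scd_profile(traj, lipid_type="POPE", window_ps=(0.0, 0.0))
        popg = scd_profile(traj, lipid_type="POPG", window_ps=(0.0, 0.0))
        np.testing.assert_array_equal(full.n_samples, pope.n_samples + popg.n_samples)


def profile_from(values, group="all", lipid_type="POPG"):
    v = np.asarray(values, dtype=float)
    return OrderParameterProfile(lipid_type, group, np.arange(2, 2 + v.size),
                                 -v, np.abs(v), np.full(v.size, 100), (0.0, 1.0))


class TestGroupComparison:
    BASE = 0.18 + 0.02 * np.sin(np.linspace(0, 3, 14))

    def test_identical_profiles_show_no_effect(self):
        rep = compare_order_groups(profile_from(self.BASE), profile_from(self.BASE))
        assert rep.t_stat == 0.0 and rep.t_p == 1.0
        assert rep.wilcoxon_p == 1.0

    def test_constant_shift_detected_by_all_three_tests(self):
        shifted = profile_from(self.BASE - 0.05)
        rep = compare_order_groups(profile_from(self.BASE), shifted)
        assert rep.wilcoxon_p < 0.05
        assert rep.t_p < 0.05
        assert rep.anova_f > 1.0 and rep.anova_p < 0.05
        assert rep.zero_variance_differences and rep.t_p == 0.0

    def test_noisy_shift_detected(self):
        rng = np.random.default_rng(8)
        shifted = profile_from(self.BASE - 0.05 + rng.normal(0, 0.003, 14))
        rep = compare_order_groups(profile_from(self.BASE), shifted)
        assert rep.wilcoxon_p < 0.05 and rep.t_p < 0.05 and rep.anova_p < 0.05
        assert np.isfinite(rep.t_stat)

    def test_anova_f_equals_unpaired_t_squared(self):
        from scipy import stats
        rng = np.random.default_rng(9)
        a = self.BASE + rng.normal(0, 0.01, 14)
        b = self.BASE - 0.03 + rng.normal(0, 0.01, 14)
        rep = compare_order_groups(profile_from(a), profile_from(b))
        t = stats.ttest_ind(np.abs(a), np.abs(b)).statistic
        assert rep.anova_f == pytest.approx(t ** 2, abs=1e-9)

    def test_too_few_pairs_error(self):
        with pytest.raises(MembraneError, match="3"):
            compare_order_groups(profile_from([0.1, 0.2]), profile_from([0.1, 0.2]))

    def test_mismatched_carbons_error(self):
        a = profile_from(self.BASE)
        b = profile_from(self.BASE[:10])
        with pytest.raises(MembraneError, match="carbon"):
            compare_order_groups(a, b)
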