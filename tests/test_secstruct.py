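import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import circvar as scipy_circvar

from pepmem.core import Frame, Trajectory
from pepmem.secstruct import (
    MissingAtomError,
    SecondaryStructureRecord,
    assign_secondary_structure,
    backbone_dihedrals,
    circular_variance,
    classify_alpha_region,
    helix_content_timeseries,
)
from pepmem.synthetic import build_ideal_peptide

from conftest import build_to_trajectory
from oracles import brute_force_hbond_set

ALPHA = (-57.0, -47.0)
PI = (-75.0, -50.0)           # clean i→i+5 Kabsch–Sander bonding under ideal geometry
AMBIG = (-65.0, -55.0)        # both i→i+4 and i→i+5 bonds: probes π-before-α precedence


class TestBackboneDihedrals:
    @pytest.mark.parametrize("phi,psi", [ALPHA, (180.0, 180.0), PI])
    def test_builder_round_trip_within_half_degree(self, phi, psi):
        traj = build_to_trajectory(build_ideal_peptide("A" * 12, phi, psi))
        s = backbone_dihedrals(traj, 0)
        np.testing.assert_allclose(s.phi[0, 1:], phi, atol=0.5)
        np.testing.assert_allclose(s.psi[0, :-1], psi, atol=0.5)

    def test_chain_termini_flagged_undefined(self):
        s = backbone_dihedrals(build_to_trajectory(build_ideal_peptide("AAAA")), 0)
        assert np.isnan(s.phi[0, 0]) and np.isnan(s.psi[0, -1])
        assert not np.isnan(s.phi[0, 1:]).any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_body_invariance(self, seed):
        build = build_ideal_peptide("AGKFLH", *ALPHA)
        traj = build_to_trajectory(build)
        ref = backbone_dihedrals(traj, 0)
        rng = np.random.default_rng(seed)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = build.coordinates @ rot.T + rng.uniform(-30, 30, 3)
        traj.frames[0] = Frame(moved + 100, traj.frames[0].box)
        got = backbone_dihedrals(Trajectory(traj.topology, [traj.frames[0]]), 0)
        np.testing.assert_allclose(got.phi[0, 1:], ref.phi[0, 1:], atol=1e-6)
        np.testing.assert_allclose(got.psi[0, :-1], ref.psi[0, :-1], atol=1e-6)

    def test_missing_backbone_atom_names_residue(self):
        traj = build_to_trajectory(build_ideal_peptide("AAAA"))
        keep = [i for i, a in enumerate(traj.topology.atoms)
                if not (a.name == "C" and a.residue_index == 3)]
        from pepmem.core import Topology
        top = Topology([traj.topology.atoms[i] for i in keep])
        traj2 = Trajectory(top, [Frame(traj.frames[0].coordinates[keep],
                                       traj.frames[0].box)])
        with pytest.raises(MissingAtomError, match="residue 3"):
            backbone_dihedrals(traj2, 0)


class TestAlphaRegion:
    @pytest.mark.parametrize("phi,psi,expected", [
        (-57.0, -47.0, True),
        (180.0, 180.0, False),
        (-90.0, -70.0, True),      # inclusive boundary
        (-35.0, -15.0, True),
        (-90.1, -47.0, False),
        (-57.0, -14.9, False),
    ])
    def test_printed_bounds_inclusive(self, phi, psi, expected):
        inside, undefined = classify_alpha_region(phi, psi)
        assert bool(inside) is expected and not undefined

    def test_undefined_input_classified_false_with_flag(self):
        inside, undefined = classify_alpha_region(np.nan, -47.0)
        assert not inside and undefined

    def test_accepted_region_lies_in_helix_sum_band(self):
        # every accepted (phi, psi) has phi+psi inside the band shared by
        # alpha and pi helices, which is why the Ramachandran analysis alone
        # cannot distinguish them
        phis = np.linspace(-90, -35, 12)
        psis = np.linspace(-70, -15, 12)
        pp, ss = np.meshgrid(phis, psis)
        inside, _ = classify_alpha_region(pp, ss)
        total = (pp + ss)[inside]
        assert total.min() >= -160.0 and total.max() <= -50.0


class TestCircularVariance:
    def test_reference_values(self):
        assert circular_variance([33.0] * 7) == pytest.approx(0.0, abs=1e-12)
        assert circular_variance([0.0, 180.0]) == pytest.approx(1.0, abs=1e-12)
        assert circular_variance([0.0, 90.0]) == pytest.approx(1 - np.sqrt(2) / 2,
                                                               abs=1e-12)

    def test_all_undefined_gives_nan_sentinel(self):
        assert np.isnan(circular_variance([np.nan, np.nan]))

    def test_matches_scipy_on_random_angles(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-180, 180, 250)
        expected = scipy_circvar(np.radians(a))
        assert circular_variance(a) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-180.0, 180.0), min_size=1, max_size=40),
           st.floats(-720.0, 720.0))
    def test_bounds_and_rotation_invariance(self, angles, shift):
        cv = circular_variance(angles)
        assert 0.0 <= cv <= 1.0
        rotated = [a + shift for a in angles]
        assert circular_variance(rotated) == pytest.approx(cv, abs=1e-9)


class TestSecondaryStructure:
    def test_ideal_alpha_helix_interior_is_H(self):
        traj = build_to_trajectory(build_ideal_peptide("A" * 12, *ALPHA))
        rec = assign_secondary_structure(traj, 0, priority="alpha_first")
        labels = rec.labels[0]
        assert set(labels[1:-1]) == {"H"}
        assert "E" not in labels and "B" not in labels

    def test_extended_chain_has_no_helix(self):
        traj = build_to_trajectory(build_ideal_peptide("A" * 10, 180.0, 180.0))
        labels = assign_secondary_structure(traj, 0).labels[0]
        assert not set(labels) & {"H", "I", "G"}

    def test_ideal_pi_helix_interior_is_I(self):
        traj = build_to_trajectory(build_ideal_peptide("A" * 14, *PI))
        labels = assign_secondary_structure(traj, 0).labels[0]
        interior = labels[2:-2]
        assert "I" in interior and set(interior) <= {"I", "T", "S", "O"}

    def test_pi_before_alpha_precedence(self):
        traj = build_to_trajectory(build_ideal_peptide("A" * 14, *AMBIG))
        pi_first = assign_secondary_structure(traj, 0, priority="pi_first").labels[0]
        alpha_first = assign_secondary_structure(traj, 0, priority="alpha_first").labels[0]
        assert "I" in pi_first and "I" not in alpha_first
        assert "H" in alpha_first

    @pytest.mark.parametrize("phi,psi,offset", [(ALPHA[0], ALPHA[1], 4),
                                                (PI[0], PI[1], 5)])
    def test_agrees_with_brute_force_hbond_oracle(self, phi, psi, offset):
        build = build_ideal_peptide("A" * 14, phi, psi)
        bonds = brute_force_hbond_set(build)
        # oracle: uniform helix bonds donor i -> acceptor i-offset
        expected_offsets = {d - a for d, a in bonds}
        assert offset in expected_offsets
        traj = build_to_trajectory(build)
        labels = assign_secondary_structure(traj, 0).labels[0]
        lab = {4: "H", 5: "I"}[offset]
        acceptors = sorted({a for d, a in bonds if d - a == offset})
        # two consecutive turns starting at the second acceptor label the run
        run_start = acceptors[1]
        assert all(labels[k - 1] == lab for k in range(run_start, run_start + offset))

    def test_missing_amide_h_reconstructed_with_notice(self):
        build = build_ideal_peptide("A" * 12, *ALPHA)
        keep = [i for i, n in enumerate(build.atom_names) if n != "H"]
        import dataclasses
        stripped = dataclasses.replace(
            build,
            atom_names=[build.atom_names[i] for i in keep],
            atom_elements=[build.atom_elements[i] for i in keep],
            atom_residues=[build.atom_residues[i] for i in keep],
            coordinates=build.coordinates[keep],
        )
        traj = build_to_trajectory(stripped)
        rec = assign_secondary_structure(traj, 0, priority="alpha_first")
        assert any("reconstructed" in n for n in rec.notices)
        assert set(rec.labels[0][1:-1]) == {"H"}

    def test_missing_carbonyl_o_is_error(self):
        build = build_ideal_peptide("AAAAA", *ALPHA)
        keep = [i for i, (n, r) in enumerate(zip(build.atom_names, build.atom_residues))
                if not (n == "O" and r == 2)]
        import dataclasses
        stripped = dataclasses.replace(
            build,
            atom_names=[build.atom_names[i] for i in keep],
            atom_elements=[build.atom_elements[i] for i in keep],
            atom_residues=[build.atom_residues[i] for i in keep],
            coordinates=build.coordinates[keep],
        )
        with pytest.raises(MissingAtomError, match="residue 2"):
            assign_secondary_structure(build_to_trajectory(stripped), 0)

    def test_kappa_undefined_near_termini_and_bounded(self):
        traj = build_to_trajectory(build_ideal_peptide("A" * 10, *ALPHA))
        rec = assign_secondary_structure(traj, 0)
        assert np.isnan(rec.kappa[0, :2]).all() and np.isnan(rec.kappa[0, -2:]).all()
        inner = rec.kappa[0, 2:-2]
        assert np.all((inner >= 0) & (inner <= 180))


class TestHelixContent:
    def _record(self, labels):
        arr = np.array(labels, dtype="U1")
        return SecondaryStructureRecord(arr, np.full(arr.shape, np.nan),
                                        np.arange(arr.shape[0], dtype=float), 0)

    def test_fractions(self):
        rec = self._record([["H"] * 12, ["O"] * 12, ["H"] * 6 + ["O"] * 6])
        np.testing.assert_allclose(helix_content_timeseries(rec), [1.0, 0.0, 0.5])

    def test_pi_and_310_count_as_helix(self):
        rec = self._record([["I", "G", "H", "O"]])
        assert helix_content_timeseries(rec)[0] == pytest.approx(0.75)
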