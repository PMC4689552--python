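import numpy as np
import pytest

from ncidyn.contact_dynamics import LifetimeClass, lifetime_class
from ncidyn.interaction_detectors import (
    ContactKind,
    detect_hbonds_frame,
    detect_hydrophobic_frame,
    detect_saltbridges_frame,
)
from ncidyn.synthetic_data import (
    ContactSchedule,
    SyntheticSpec,
    expected_condition_diff,
    make_condition_pair,
    make_hb_geometry_frame,
    make_scripted_trajectory,
    make_toy_topology,
)
from ncidyn.topology_model import build_participant_sets

SEQ = (
    "ASP", "LYS", "SER", "GLY", "LEU", "VAL", "ARG",
    "GLU", "HIS", "TRP", "ASN", "GLN", "TYR", "THR",
)


class TestToyTopology:
    def test_sidechain_atoms_present(self, toy_topology):
        names = {
            (toy_topology.residue_of(a.index).name, a.name) for a in toy_topology.atoms
        }
        assert ("ASP", "OD1") in names and ("ASP", "OD2") in names
        assert ("LYS", "NZ") in names
        assert ("ARG", "NH2") in names

    def test_histidine_contributes_no_sb_participants(self):
        spec = SyntheticSpec(residue_sequence=("HIS",), n_waters=0)
        parts = build_participant_sets(make_toy_topology(spec))
        assert not parts.sb_negative and not parts.sb_positive

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            make_toy_topology(SyntheticSpec(residue_sequence=("ZZZ",)))

    def test_every_template_residue_passes_invariants(self):
        all_residues = (
            "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
            "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        )
        topo = make_toy_topology(SyntheticSpec(residue_sequence=all_residues, n_waters=5))
        topo.validate()  # raises on violation
        # proline's backbone N carries no hydrogen
        pro = next(r.index for r in topo.residues if r.name == "PRO")
        pro_n = next(
            a.index for a in topo.atoms if a.residue_index == pro and a.name == "N"
        )
        assert pro_n not in topo.donor_hydrogens

    def test_home_positions_have_no_contacts(self, toy_topology, toy_participants):
        from ncidyn.trajectory_io import Frame

        frame = Frame(0.0, toy_topology.reference_coordinates.copy())
        assert not detect_saltbridges_frame(frame, toy_topology, toy_participants).contacts
        assert not detect_hbonds_frame(frame, toy_topology, toy_participants).contacts
        assert not detect_hydrophobic_frame(frame, toy_topology, toy_participants).contacts


class TestScriptedTrajectory:
    def test_target_percentage_realized(self, toy_spec, standard_schedules):
        spec = SyntheticSpec(
            residue_sequence=toy_spec.residue_sequence, n_waters=3, n_frames=100,
            seed=5, schedules=(
                ContactSchedule(ContactKind.SB, anchor=(0, "OD1"), mobile=(1, "NZ"), pattern=37.0),
            ),
        )
        _, truth = make_scripted_trajectory(spec)
        assert truth.contacts[0].percent == pytest.approx(37.0)

    def test_zero_schedules_no_contacts(self, toy_spec):
        spec = SyntheticSpec(
            residue_sequence=toy_spec.residue_sequence, n_waters=3, n_frames=10, seed=2
        )
        traj, truth = make_scripted_trajectory(spec)  # verify=True checks every frame
        assert truth.contacts == []

    def test_same_seed_identical_different_seed_differs(self, toy_spec, standard_schedules):
        base = dict(
            residue_sequence=toy_spec.residue_sequence, n_waters=3, n_frames=10,
            schedules=standard_schedules,
        )
        t1, _ = make_scripted_trajectory(SyntheticSpec(**base, seed=9))
        t2, _ = make_scripted_trajectory(SyntheticSpec(**base, seed=9))
        t3, _ = make_scripted_trajectory(SyntheticSpec(**base, seed=10))
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1.coordinates, f2.coordinates)
        assert any(
            not np.array_equal(f1.coordinates, f3.coordinates)
            for f1, f3 in zip(t1.frames, t3.frames)
        )

    def test_shared_atom_schedules_rejected(self, toy_spec):
        schedules = (
            ContactSchedule(ContactKind.SB, anchor=(0, "OD1"), mobile=(1, "NZ")),
            ContactSchedule(ContactKind.SB, anchor=(0, "OD1"), mobile=(6, "NH1")),
        )
        spec = SyntheticSpec(
            residue_sequence=toy_spec.residue_sequence, n_waters=3, n_frames=10,
            seed=0, schedules=schedules,
        )
        with pytest.raises(ValueError, match="share atoms"):
            make_scripted_trajectory(spec)

    def test_acceptor_that_is_donor_rejected(self, toy_spec):
        # Ser OG as mobile acceptor carries a hydrogen: reverse bond risk
        schedules = (
            ContactSchedule(ContactKind.HB, anchor=(13, "OG1"), mobile=(2, "OG")),
        )
        spec = SyntheticSpec(
            residue_sequence=toy_spec.residue_sequence, n_waters=3, n_frames=10,
            seed=0, schedules=schedules,
        )
        with pytest.raises(ValueError, match="itself a donor"):
            make_scripted_trajectory(spec)

    def test_noise_amplitude_bound_enforced(self, toy_spec):
        with pytest.raises(ValueError, match="noise"):
            SyntheticSpec(
                residue_sequence=toy_spec.residue_sequence, noise_amplitude=0.03
            )


class TestHbGeometryFrame:
    @pytest.mark.parametrize("d,angle", [(0.35, 120.0), (0.30, 150.0), (0.30, 180.0), (0.2, 95.0)])
    def test_constructed_geometry_is_exact(self, d, angle):
        frame = make_hb_geometry_frame(d, angle)
        dd, h, a = frame.coordinates
        assert np.linalg.norm(dd - a) == pytest.approx(d, abs=1e-12)
        v1, v2 = dd - h, a - h
        cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        measured = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert measured == pytest.approx(angle, abs=1e-7)
        assert np.linalg.norm(dd - h) == pytest.approx(0.1)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_hb_geometry_frame(0.05, 150.0)
        with pytest.raises(ValueError):
            make_hb_geometry_frame(0.3, 0.0)


class TestConditionPair:
    def _specs(self):
        base = dict(residue_sequence=SEQ, n_waters=3, n_frames=100)
        spec_a = SyntheticSpec(
            **base, seed=31,
            schedules=(
                ContactSchedule(ContactKind.SB, anchor=(0, "OD1"), mobile=(1, "NZ"), pattern=95.0),
                ContactSchedule(ContactKind.SB, anchor=(0, "OD2"), mobile=(6, "NH1"), pattern=95.0),
                ContactSchedule(ContactKind.SB, anchor=(7, "OE1"), mobile=(6, "NH2"), pattern=95.0),
            ),
        )
        spec_b = SyntheticSpec(
            **base, seed=32,
            schedules=(
                # the three long-lived bridges shortened to 50%
                ContactSchedule(ContactKind.SB, anchor=(0, "OD1"), mobile=(1, "NZ"), pattern=50.0),
                ContactSchedule(ContactKind.SB, anchor=(0, "OD2"), mobile=(6, "NH1"), pattern=50.0),
                ContactSchedule(ContactKind.SB, anchor=(7, "OE1"), mobile=(6, "NH2"), pattern=50.0),
                # plus a new hydrophobic contact
                ContactSchedule(ContactKind.HP, anchor=(4, "CD1"), mobile=(5, "CG1"), pattern=25.0),
            ),
        )
        return spec_a, spec_b

    def test_identical_specs_zero_diff(self):
        base = dict(residue_sequence=SEQ, n_waters=3, n_frames=20, seed=1)
        spec = SyntheticSpec(**base)
        (_, gta), (_, gtb) = make_condition_pair(spec, spec)
        diff = expected_condition_diff(gta, gtb)
        for kind in diff.values():
            assert kind["d_unique"] == 0
            assert kind["d_time_averaged"] == 0.0

    def test_lifetime_shift_manifest(self):
        spec_a, spec_b = self._specs()
        (_, gta), (_, gtb) = make_condition_pair(spec_a, spec_b)
        diff = expected_condition_diff(gta, gtb)
        assert diff["SB"]["d_unique"] == 0
        assert diff["SB"]["d_lifetime"] == {"short": 0, "substantial": 3, "long": -3}
        assert diff["HP"]["d_unique"] == 1

    def test_topology_mismatch_rejected(self):
        a = SyntheticSpec(residue_sequence=("GLY", "ALA"), n_waters=0)
        b = SyntheticSpec(residue_sequence=("GLY", "SER"), n_waters=0)
        with pytest.raises(ValueError, match="topology"):
            make_condition_pair(a, b)


def test_ground_truth_classes_match_percentages(standard_schedules, toy_spec):
    spec = SyntheticSpec(
        residue_sequence=toy_spec.residue_sequence, n_waters=3, n_frames=50,
        seed=4, schedules=standard_schedules,
    )
    _, truth = make_scripted_trajectory(spec)
    for contact in truth.contacts:
        assert lifetime_class(contact.percent) in LifetimeClass
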