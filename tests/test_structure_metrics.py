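import numpy as np
import pytest
from oracles import isolated_sphere_area, two_sphere_areas

from conftest import ca_chain_topology, ca_trajectory
from ncidyn.structure_metrics import (
    ca_distance_matrix,
    kabsch_superpose,
    matrix_difference,
    rmsd_ca,
    rmsf_ca,
    sasa_by_class,
    shrake_rupley_sasa,
)
from ncidyn.topology_model import (
    AtomRecord,
    AtomRole,
    ResidueRecord,
    Topology,
    classify_residue,
)
from ncidyn.trajectory_io import Frame


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        rot, trans, fitted = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        np.testing.assert_allclose(fitted, pts, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_known_rotation(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(12, 3))
        rot_true = _random_rotation(seed + 50)
        mobile = ref @ rot_true.T + rng.normal(size=3)
        rot, _, fitted = kabsch_superpose(mobile, ref)
        np.testing.assert_allclose(fitted, ref, atol=1e-8)
        np.testing.assert_allclose(rot @ rot_true, np.eye(3), atol=1e-8)

    def test_reflection_yields_proper_rotation(self):
        ref = np.random.default_rng(3).normal(size=(8, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_collinear_set_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line + 1.0)

    def test_too_few_atoms_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError, match="3 atoms"):
            kabsch_superpose(pts, pts)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_mdanalysis_rotation(self, seed):
        """Independent cross-check against MDAnalysis's superposition."""
        from MDAnalysis.analysis.align import rotation_matrix

        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(20, 3))
        mobile = ref @ _random_rotation(seed).T + rng.normal(size=3) * 0.1
        rot, _, _ = kabsch_superpose(mobile, ref)
        r_mda, _ = rotation_matrix(mobile - mobile.mean(0), ref - ref.mean(0))
        np.testing.assert_allclose(rot, r_mda, atol=1e-6)


class TestRmsd:
    def _frames(self, coords_a, coords_b):
        topo = ca_chain_topology(coords_a.shape[0])
        return Frame(0.0, coords_a), Frame(1.0, coords_b), topo

    def test_zero_against_itself(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        f, ref, topo = self._frames(pts, pts.copy())
        assert rmsd_ca(f, ref, topo) == pytest.approx(0.0, abs=1e-9)
        assert rmsd_ca(f, ref, topo, fit=False) == 0.0

    def test_rigid_motion_removed_by_fit(self):
        pts = np.random.default_rng(2).normal(size=(6, 3))
        moved = pts @ _random_rotation(9).T + np.array([1.0, 0.0, 0.0])
        f, ref, topo = self._frames(moved, pts)
        assert rmsd_ca(f, ref, topo, fit=True) == pytest.approx(0.0, abs=1e-7)
        assert rmsd_ca(f, ref, topo, fit=False) > 1.0

    def test_two_atom_closed_form(self):
        # one of two Cα displaced by d without fitting -> RMSD d/sqrt(2)
        d = 0.3  # nm
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = a.copy()
        b[1, 1] += d
        f, ref, topo = self._frames(b, a)
        expected_angstrom = d / np.sqrt(2) * 10
        assert rmsd_ca(f, ref, topo, fit=False) == pytest.approx(expected_angstrom)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        pts = np.random.default_rng(4).normal(size=(5, 3))
        traj = ca_trajectory([pts] * 4)
        np.testing.assert_allclose(rmsf_ca(traj), 0.0, atol=1e-12)

    def test_oscillation_closed_form(self):
        # one Cα alternating +/- d about its reference along one axis
        d = 0.25  # nm
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [1.0, 1.0, 0]])
        stack = []
        for sign in (1, -1, 1, -1):
            c = base.copy()
            c[2, 2] = sign * d
            stack.append(c)
        traj = ca_trajectory(stack)
        # fit=False keeps the scripted displacement exact
        rmsf = rmsf_ca(traj, reference_mode="initial", fit=False)
        # reference = first frame (at +d), so deviations are 0 and 2d
        assert rmsf[2] == pytest.approx(np.sqrt((0 + (2 * d) ** 2 * 2) / 4) * 10)
        mean_ref = rmsf_ca(traj, reference_mode="mean", fit=False)
        assert mean_ref[2] == pytest.approx(d * 10)
        np.testing.assert_allclose(np.delete(mean_ref, 2), 0.0, atol=1e-12)

    def test_single_frame_rejected(self):
        traj = ca_trajectory([np.random.default_rng(0).normal(size=(4, 3))])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_ca(traj)


class TestDistanceMatrix:
    def test_single_frame_line(self):
        coords = np.array([[0.0, 0, 0], [0.4, 0, 0], [0.8, 0, 0]])
        traj = ca_trajectory([coords])
        m = ca_distance_matrix(traj)
        assert m.values[0, 2] == pytest.approx(0.8)
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 0.0)

    def test_time_average(self):
        a = np.array([[0.0, 0, 0], [0.4, 0, 0], [1.0, 0, 0]])
        b = a.copy()
        b[1, 0] = 0.6
        m = ca_distance_matrix(ca_trajectory([a, b]))
        assert m.values[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_frame_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        stack = rng.normal(size=(4, 6, 3))
        m = ca_distance_matrix(ca_trajectory(stack))
        want = np.zeros((6, 6))
        for frame in stack:
            for i in range(6):
                for j in range(6):
                    want[i, j] += np.linalg.norm(frame[i] - frame[j])
        np.testing.assert_allclose(m.values, want / 4, atol=1e-12)

    def test_difference_and_flags(self):
        rng = np.random.default_rng(5)
        stack = rng.normal(size=(2, 5, 3))
        a = ca_distance_matrix(ca_trajectory(stack))
        b = ca_distance_matrix(ca_trajectory(stack + 0.0))
        diff, flags = matrix_difference(a, b)
        np.testing.assert_allclose(diff.values, 0.0, atol=1e-12)
        assert flags == []
        # perturb one pair beyond the 1 nm flag threshold
        stack2 = stack.copy()
        stack2[:, 4] += 3.0
        c = ca_distance_matrix(ca_trajectory(stack2))
        diff2, flags2 = matrix_difference(c, a)
        assert any(4 in (i, j) for i, j, _ in flags2)
        diff3, _ = matrix_difference(a, c)
        np.testing.assert_allclose(diff2.values, -diff3.values)

    def test_label_mismatch_rejected(self):
        a = ca_distance_matrix(ca_trajectory(np.zeros((1, 4, 3)) + np.arange(4)[:, None]))
        b = ca_distance_matrix(ca_trajectory(np.zeros((1, 5, 3)) + np.arange(5)[:, None]))
        with pytest.raises(ValueError, match="labels"):
            matrix_difference(a, b)


def _atom_topology(elements, res_names=None):
    """One-atom-per-residue topology for SASA micro-systems."""
    res_names = res_names or ["ALA"] * len(elements)
    residues = [
        ResidueRecord(i, name, "A", i + 1, classify_residue(name))
        for i, name in enumerate(res_names)
    ]
    atoms = [
        AtomRecord(i, "CB" if e == "C" else e, e, i, AtomRole.SIDECHAIN)
        for i, e in enumerate(elements)
    ]
    return Topology(atoms=atoms, residues=residues)


class TestSasa:
    PROBE = 0.14

    def test_isolated_sphere(self):
        topo = _atom_topology(["N"])
        frame = Frame(0.0, np.zeros((1, 3)))
        result = shrake_rupley_sasa(frame, topo, probe=self.PROBE)
        want = isolated_sphere_area(0.155, self.PROBE)
        assert result.atom_areas[0] == pytest.approx(want, rel=0.01)

    def test_fully_enclosed_atom(self):
        # a tight octahedral cage of sulfurs around a carbon
        d = 0.25
        cage = np.array(
            [[d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0], [0, 0, d], [0, 0, -d]]
        )
        coords = np.vstack([[0.0, 0.0, 0.0], cage])
        topo = _atom_topology(["C"] + ["S"] * 6)
        result = shrake_rupley_sasa(Frame(0.0, coords), topo, probe=self.PROBE)
        assert result.atom_areas[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("d", [0.15, 0.25, 0.35])
    def test_two_sphere_closed_form(self, d):
        topo = _atom_topology(["C", "C"])
        frame = Frame(0.0, np.array([[0.0, 0, 0], [d, 0, 0]]))
        result = shrake_rupley_sasa(frame, topo, probe=self.PROBE)
        want1, want2 = two_sphere_areas(0.170, 0.170, d, self.PROBE)
        assert result.atom_areas[0] == pytest.approx(want1, rel=0.02)
        assert result.atom_areas[1] == pytest.approx(want2, rel=0.02)

    def test_occluder_never_increases_area(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 0.8, size=(5, 3))
        topo5 = _atom_topology(["C"] * 5)
        before = shrake_rupley_sasa(Frame(0.0, coords), topo5).atom_areas[:5]
        topo6 = _atom_topology(["C"] * 6)
        added = np.vstack([coords, coords.mean(axis=0)])
        after = shrake_rupley_sasa(Frame(0.0, added), topo6).atom_areas[:5]
        assert np.all(after <= before + 1e-12)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 0.6, size=(4, 3))
        topo = _atom_topology(["C", "N", "O", "S"])
        coarse = shrake_rupley_sasa(Frame(0.0, coords), topo, n_points=960)
        fine = shrake_rupley_sasa(Frame(0.0, coords), topo, n_points=4000)
        total_c, total_f = coarse.atom_areas.sum(), fine.atom_areas.sum()
        assert abs(total_f - total_c) / total_f < 0.01

    def test_water_excluded(self, toy_topology):
        frame = Frame(0.0, toy_topology.reference_coordinates.copy())
        result = shrake_rupley_sasa(frame, toy_topology)
        water_atoms = [
            a.index for a in toy_topology.atoms
            if toy_topology.residue_of(a.index).is_water
        ]
        assert np.all(result.atom_areas[water_atoms] == 0.0)

    def test_class_totals_partition(self, toy_topology):
        frame = Frame(0.0, toy_topology.reference_coordinates.copy())
        result = shrake_rupley_sasa(frame, toy_topology)
        totals = sasa_by_class(result, toy_topology)
        other_area = sum(
            area for ri, area in result.residue_areas.items()
            if toy_topology.residues[ri].is_protein
            and toy_topology.residues[ri].res_class.value == "other"
        )
        # pho + phil + OTHER-class residues = total (His counts only in total)
        assert totals["hydrophobic"] + totals["hydrophilic"] + other_area == pytest.approx(
            totals["total"], abs=1e-9
        )
        assert other_area > 0  # His is present and exposed

    def test_all_hydrophobic_means_zero_hydrophilic(self):
        topo = _atom_topology(["C", "C"], ["ALA", "LEU"])
        frame = Frame(0.0, np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        totals = sasa_by_class(shrake_rupley_sasa(frame, topo), topo)
        assert totals["hydrophilic"] == 0.0
        assert totals["hydrophobic"] == pytest.approx(totals["total"])
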