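"""Kabsch superposition, Calpha pairing and the anchored RMSD matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from branchkit.errors import DegeneracyError, PairingError
from branchkit.io import BranchModel
from branchkit.superpose import (
    anchored_rmsd_matrix,
    kabsch_superpose,
    pair_common_ca,
    rmsd_between_subunits,
)
from conftest import atoms_from_xyz
from oracles import quaternion_superpose_rmsd


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestKabsch:
    def test_identity_case(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        tr, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_known_transform_recovery(self):
        rng = np.random.default_rng(1)
        moving = rng.normal(size=(25, 3)) * 10
        R = random_rotation(rng)
        t = np.array([5.0, -3.0, 12.0])
        fixed = moving @ R.T + t
        tr, rmsd = kabsch_superpose(moving, fixed)
        np.testing.assert_allclose(tr.rotation, R, atol=1e-9)
        np.testing.assert_allclose(tr.translation, t, atol=1e-8)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        moving = rng.normal(size=(10, 3)) * 8
        fixed = rng.normal(size=(10, 3)) * 8
        _, rmsd = kabsch_superpose(moving, fixed)
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(moving, fixed), abs=1e-9)

    def test_rotation_is_always_proper(self):
        # near-planar sets are where a reflection would sneak in
        rng = np.random.default_rng(3)
        for _ in range(10):
            moving = rng.normal(size=(6, 3))
            fixed = rng.normal(size=(6, 3))
            fixed[:, 2] *= 1e-4
            tr, _ = kabsch_superpose(moving, fixed)
            assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_is_pairing_error(self):
        with pytest.raises(PairingError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_too_few_points_is_degeneracy_error(self):
        with pytest.raises(DegeneracyError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_are_degenerate(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegeneracyError):
            kabsch_superpose(line, line)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_rmsd_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(12, 3)) * 5
        b = rng.normal(size=(12, 3)) * 5
        _, rmsd0 = kabsch_superpose(a, b)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 20
        _, rmsd1 = kabsch_superpose(a @ R.T + t, b @ R.T + t)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_rmsd_is_symmetric(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(15, 3)) * 6
        b = rng.normal(size=(15, 3)) * 6
        _, ab = kabsch_superpose(a, b)
        _, ba = kabsch_superpose(b, a)
        assert ab == pytest.approx(ba, abs=1e-9)


class TestPairing:
    def test_identical_subunits_pair_fully_in_order(self, monomer):
        a, b, paired = pair_common_ca(monomer.atoms, monomer.atoms)
        assert len(a) == len(monomer.atoms)
        assert list(paired["residue_a"]) == sorted(paired["residue_a"])

    def test_residue_number_mode_intersects_numbering(self):
        xyz = np.random.default_rng(0).normal(size=(100, 3))
        a = atoms_from_xyz(xyz, start_residue=1)  # residues 1..100
        b = atoms_from_xyz(xyz, start_residue=51)  # residues 51..150
        ca, cb, paired = pair_common_ca(a, b, mode="residue_number")
        assert len(ca) == 50
        assert paired["residue_a"].min() == 51 and paired["residue_a"].max() == 100

    def test_sequence_alignment_mode_bridges_offset_numbering(self):
        rng = np.random.default_rng(4)
        names = [["ALA", "GLY", "SER", "VAL", "LEU"][i % 5] for i in range(60)]
        xyz = rng.normal(size=(60, 3)) * 10
        a = atoms_from_xyz(xyz, start_residue=1, residue_names=names)
        b = atoms_from_xyz(xyz, start_residue=201, residue_names=names)
        ca, cb, paired = pair_common_ca(a, b, mode="sequence_alignment")
        assert len(ca) == 60  # full-length pairing despite disjoint numbering
        np.testing.assert_allclose(ca, cb)

    def test_disjoint_numbering_fails_in_residue_mode(self):
        xyz = np.zeros((10, 3))
        a = atoms_from_xyz(xyz, start_residue=1)
        b = atoms_from_xyz(xyz, start_residue=100)
        with pytest.raises(PairingError):
            pair_common_ca(a, b, mode="residue_number")

    def test_unknown_mode_rejected(self, monomer):
        with pytest.raises(ValueError):
            pair_common_ca(monomer.atoms, monomer.atoms, mode="magic")


class TestRMSDBetweenSubunits:
    def test_identical_subunits_give_zero(self, branch_with_truth):
        model, _ = branch_with_truth
        rmsd, n = rmsd_between_subunits(model, "M1", model.subunits["M1"])
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert n == len(model.subunits["M1"])

    def test_symmetry_transformed_copy_gives_zero(self, branch_with_truth):
        # subunit M2 is M1 under the helical screw: post-fit RMSD must vanish
        model, _ = branch_with_truth
        rmsd, _ = rmsd_between_subunits(model, "M2", model.subunits["M1"])
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pruning_drops_outlier_pairs(self, monomer):
        df = monomer.atoms.df.copy()
        moved = monomer.atoms.with_coords(monomer.atoms.coords)
        # displace three residues far away, leave the rest identical
        xyz = moved.coords
        xyz[:3] += 60.0
        moved = moved.with_coords(xyz)
        model = BranchModel({"M1": moved}, provenance="t")
        rmsd_all, n_all = rmsd_between_subunits(model, "M1", monomer.atoms)
        rmsd_pruned, n_pruned = rmsd_between_subunits(
            model, "M1", monomer.atoms, prune=True
        )
        assert rmsd_all > 1.0
        assert n_pruned == n_all - 3
        assert rmsd_pruned == pytest.approx(0.0, abs=1e-6)


class TestAnchoredMatrix:
    def test_model_against_itself_is_zero(self, branch_with_truth):
        model, _ = branch_with_truth
        labels = model.labels_with_role("complex")
        mat = anchored_rmsd_matrix(model, model, labels)
        assert mat.anchors == labels and mat.targets == labels
        np.testing.assert_allclose(mat.values, 0.0, atol=1e-9)

    def test_rotated_second_subunit_matches_brute_force(self):
        """Two-subunit toy: B's subunit 2 rotated 10 deg about an axis through
        subunit 1's centroid. Anchoring on 1 must give ~0 for (1,1) and the
        explicitly computed displacement RMSD for (1,2)."""
        rng = np.random.default_rng(11)
        s1 = rng.normal(size=(30, 3)) * 8
        s2 = rng.normal(size=(30, 3)) * 8 + np.array([30.0, 0.0, 0.0])
        c1 = s1.mean(axis=0)
        ang = np.radians(10.0)
        R = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        s2_rot = (s2 - c1) @ R.T + c1
        model_a = BranchModel(
            {"M1": atoms_from_xyz(s1), "M2": atoms_from_xyz(s2)}, provenance="a"
        )
        model_b = BranchModel(
            {"M1": atoms_from_xyz(s1), "M2": atoms_from_xyz(s2_rot)}, provenance="b"
        )
        mat = anchored_rmsd_matrix(model_a, model_b, ["M1", "M2"])
        assert mat.values[0, 0] == pytest.approx(0.0, abs=1e-9)
        expected = float(np.sqrt(np.mean(np.sum((s2_rot - s2) ** 2, axis=1))))
        assert mat.values[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_diagonal_is_row_minimum_for_rigid_subcomplex_motion(self):
        """Move one rigid group of subunits relative to another: each anchor's
        own column must be its row minimum."""
        rng = np.random.default_rng(21)
        subs = {f"M{i+1}": rng.normal(size=(25, 3)) * 7 + i * 25.0 for i in range(4)}
        model_a = BranchModel(
            {k: atoms_from_xyz(v) for k, v in subs.items()}, provenance="a"
        )
        R = random_rotation(rng)
        moved = {
            k: (v @ R.T + 8.0 if k in ("M3", "M4") else v) for k, v in subs.items()
        }
        model_b = BranchModel(
            {k: atoms_from_xyz(v) for k, v in moved.items()}, provenance="b"
        )
        mat = anchored_rmsd_matrix(model_a, model_b, list(subs))
        for i in range(len(subs)):
            assert mat.values[i, i] == pytest.approx(mat.values[i].min(), abs=1e-9)

    def test_missing_label_names_the_subunit(self, branch_with_truth):
        model, _ = branch_with_truth
        partial = BranchModel(
            {k: v for k, v in model.subunits.items() if k != "ARP2"}, provenance="p"
        )
        with pytest.raises(PairingError, match="ARP2"):
            anchored_rmsd_matrix(model, partial, model.labels_with_role("complex"))

    def test_serialization_round_trip(self, branch_with_truth, tmp_path):
        model, _ = branch_with_truth
        mat = anchored_rmsd_matrix(model, model, ["M1", "M2"])
        path = tmp_path / "mat.csv"
        mat.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == ["anchor", "target", "rmsd", "n_pairs"]
        assert len(back) == 4


class TestNoiseRMSD:
    def test_post_fit_rmsd_tracks_sigma_sqrt3(self):
        """Per-coordinate Gaussian noise of std sigma on n >= 500 points gives a
        post-fit RMSD of ~ sigma*sqrt(3) (3 sigma^2 expected squared displacement
        per atom, minus a small amount absorbed by the fitted transform)."""
        rng = np.random.default_rng(123)
        pts = rng.uniform(-50, 50, size=(1000, 3))
        sigma = 0.5
        noisy = pts + rng.normal(scale=sigma, size=pts.shape)
        _, rmsd = kabsch_superpose(noisy, pts)
        assert rmsd == pytest.approx(sigma * np.sqrt(3.0), rel=0.10)
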