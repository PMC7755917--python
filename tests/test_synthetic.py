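"""Synthetic branched-filament generator: determinism, geometry, ground truth."""

import numpy as np
import pytest

from branchkit.errors import ParameterError
from branchkit.geometry import AxisSpec, axis_vector, branch_angle
from branchkit.io import SubunitMapping, assign_subunits, read_structure, write_mapping_for, write_model_pdb
from branchkit.superpose import kabsch_superpose, pair_common_ca
from branchkit.synthetic import (
    REFERENCE_RESIDUE,
    BranchSpec,
    FilamentSpec,
    build_branch,
    build_filament,
    default_complex_monomers,
    make_toy_monomer,
    perturb_model,
    standard_branch,
)


class TestToyMonomer:
    def test_deterministic_for_a_seed(self):
        a = make_toy_monomer(50, 25.0, seed=7)
        b = make_toy_monomer(50, 25.0, seed=7)
        np.testing.assert_array_equal(a.atoms.coords, b.atoms.coords)

    def test_reference_atom_at_origin_with_reference_residue(self):
        mono = make_toy_monomer(20, 10.0, seed=1)
        df = mono.atoms.df
        ref = df[df["residue_number"] == REFERENCE_RESIDUE]
        assert len(ref) == 1
        np.testing.assert_array_equal(ref[["x", "y", "z"]].to_numpy()[0], 0.0)

    def test_atoms_stay_within_radius(self):
        mono = make_toy_monomer(200, 12.0, seed=3)
        assert (np.linalg.norm(mono.atoms.coords, axis=1) <= 12.0 + 1e-9).all()

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ParameterError):
            make_toy_monomer(3, 10.0, seed=0)


class TestFilament:
    def test_reference_atoms_lie_on_axis_at_rise_spacing(self, monomer):
        spec = FilamentSpec(rise=27.5, twist=-166.7, n_subunits=8)
        fil = build_filament(monomer, spec)
        for k, label in enumerate(spec.labels):
            df = fil.subunits[label].df
            ref = df[df["residue_number"] == REFERENCE_RESIDUE]
            np.testing.assert_allclose(
                ref[["x", "y", "z"]].to_numpy()[0], [0.0, 0.0, k * 27.5], atol=1e-9
            )

    def test_consecutive_subunits_related_by_screw_symmetry(self, monomer):
        fil = build_filament(monomer, FilamentSpec(n_subunits=4))
        # superposing subunit k onto k+1 must be exact (RMSD 0)
        a, b, _ = pair_common_ca(fil.subunits["M2"], fil.subunits["M3"])
        _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_axis_vector_is_plus_z(self, monomer):
        fil = build_filament(monomer, FilamentSpec(n_subunits=8))
        v, _ = axis_vector(fil, AxisSpec("M1", "M8"))
        np.testing.assert_allclose(v, [0, 0, 1], atol=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            FilamentSpec(rise=-1.0)
        with pytest.raises(ParameterError):
            FilamentSpec(n_subunits=1)


class TestBranch:
    def test_constructed_angle_is_exact(self, monomer):
        model, truth = build_branch(
            FilamentSpec(n_subunits=8),
            FilamentSpec(n_subunits=3, role_prefix="D"),
            BranchSpec(theta=71.0),
            monomer,
        )
        assert branch_angle(model).theta == pytest.approx(71.0, abs=1e-6)
        assert truth.theta == 71.0
        cos = float(np.dot(truth.mother_axis, truth.daughter_axis))
        assert np.degrees(np.arccos(cos)) == pytest.approx(71.0, abs=1e-9)

    def test_rigid_motion_of_whole_model_preserves_angle(self, branch_with_truth):
        model, _ = branch_with_truth
        moved = model.transformed(lambda x: x + np.array([100.0, -50.0, 10.0]))
        assert branch_angle(moved).theta == pytest.approx(71.0, abs=1e-6)

    def test_invalid_attachment_label_rejected(self, monomer):
        with pytest.raises(ParameterError):
            build_branch(
                FilamentSpec(n_subunits=4),
                FilamentSpec(n_subunits=3, role_prefix="D"),
                BranchSpec(attachment_subunit="M9"),
                monomer,
            )

    def test_blob_placed_far_away_never_contacts(self, monomer):
        """A complex blob placed with every atom >= 12 Å from every mother
        Calpha is absent from the 10 Å contacting set by construction."""
        from branchkit.contacts import ca_contacts, contacting_subunit_summary

        blobs = default_complex_monomers(n_atoms=10, radius=5.0, seed=50)
        centers = {label: np.array([500.0 + 30 * i, 0.0, 0.0]) for i, label in enumerate(blobs)}
        centers["ARP2"] = np.array([25.0, 0.0, 82.5])  # near the junction
        model, truth = build_branch(
            FilamentSpec(n_subunits=8),
            FilamentSpec(n_subunits=3, role_prefix="D"),
            BranchSpec(theta=71.0),
            monomer,
            complex_monomers=blobs,
            complex_centers=centers,
        )
        cmap = ca_contacts(
            model, model.labels_with_role("complex"), model.labels_with_role("mother")
        )
        contacting = contacting_subunit_summary(cmap).contacting_a
        assert contacting <= {"ARP2"}
        assert truth.complex_centers["ARP3"][0] >= 500.0

    def test_ground_truth_sufficient_to_rederive_daughter(self, branch_with_truth):
        """Applying the recorded rotation+translation to a freshly built
        daughter frame reproduces the model's daughter coordinates."""
        model, truth = branch_with_truth
        mono = make_toy_monomer(50, 14.0, truth.monomer_seed)
        frame = build_filament(mono, truth.daughter_spec)
        for label in ("D1", "D2", "D3"):
            rebuilt = frame.subunits[label].coords @ truth.daughter_rotation.T + truth.daughter_translation
            np.testing.assert_allclose(rebuilt, model.subunits[label].coords, atol=1e-9)


class TestPerturb:
    def test_sigma_zero_is_identity(self, branch_with_truth):
        model, _ = branch_with_truth
        same = perturb_model(model, 0.0, seed=9)
        for label in model.labels:
            np.testing.assert_array_equal(
                same.subunits[label].coords, model.subunits[label].coords
            )

    def test_same_seed_reproduces(self, branch_with_truth):
        model, _ = branch_with_truth
        a = perturb_model(model, 0.5, seed=4)
        b = perturb_model(model, 0.5, seed=4)
        for label in model.labels:
            np.testing.assert_array_equal(a.subunits[label].coords, b.subunits[label].coords)

    def test_negative_sigma_rejected(self, branch_with_truth):
        model, _ = branch_with_truth
        with pytest.raises(ParameterError):
            perturb_model(model, -0.1, seed=0)

    def test_post_fit_rmsd_matches_sigma_sqrt3(self):
        model, _ = standard_branch(seed=3, monomer_atoms=100, with_complex=True)
        noisy = perturb_model(model, 0.5, seed=8)
        a = model.atom_table().coords
        b = noisy.atom_table().coords
        assert len(a) >= 1000
        _, rmsd = kabsch_superpose(b, a)
        assert rmsd == pytest.approx(0.5 * np.sqrt(3.0), rel=0.10)


def test_generator_output_round_trips_through_pdb(tmp_path, branch_with_truth):
    model, truth = branch_with_truth
    path = tmp_path / "branch.pdb"
    chains = write_model_pdb(model, path)
    mapping_path = tmp_path / "branch.mapping"
    write_mapping_for(chains, mapping_path)
    model2 = assign_subunits(read_structure(path), SubunitMapping.from_file(mapping_path))
    assert model2.labels == model.labels
    for label in model.labels:
        np.testing.assert_allclose(
            model2.subunits[label].coords, model.subunits[label].coords, atol=5e-4
        )
    # the written model still reproduces the ground-truth angle (3-decimal coords)
    assert branch_angle(model2).theta == pytest.approx(truth.theta, abs=1e-2)
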