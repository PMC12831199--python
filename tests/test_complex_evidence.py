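"""complex_evidence: PAE parsing, contacts, helicity, orientation."""

import json

import numpy as np
import pytest

from slimscan.complex_evidence import (
    DEFAULT_SPA2_GROOVE,
    EvidenceError,
    GrooveDefinition,
    ORIENT_CANONICAL,
    ORIENT_FLIPPED,
    ORIENT_INDETERMINATE,
    ORIENT_NOT_APPLICABLE,
    PAEMatrix,
    classify_orientation,
    gather_evidence,
    interchain_contacts,
    interface_pae_summary,
    motif_helicity_in_complex,
    read_pae_matrix,
)
from slimscan.geometry import random_rotation
from slimscan.synthetic_data import LIGAND_MOTIF_START, transform_model

MOTIF_START = LIGAND_MOTIF_START


class TestPAEParsing:
    def test_flat_dialect(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({
            "predicted_aligned_error": [[5.0] * 10] * 10, "chain_boundary": 6,
        }))
        pae = read_pae_matrix(path)
        assert pae.n == 10 and pae.chain_boundary == 6
        assert np.all(pae.matrix == 5.0)

    def test_ragged_matrix_rejected(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({
            "predicted_aligned_error": [[1.0] * 9] + [[1.0] * 10] * 9,
            "chain_boundary": 6,
        }))
        with pytest.raises(EvidenceError, match="ragged|square"):
            read_pae_matrix(path)

    def test_negative_entries_rejected(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({
            "predicted_aligned_error": [[-1.0, 1.0], [1.0, 1.0]], "chain_boundary": 1,
        }))
        with pytest.raises(EvidenceError, match="non-negative"):
            read_pae_matrix(path)

    def test_paired_array_dialect_equals_flat(self, tmp_path):
        rng = np.random.default_rng(1)
        m = np.round(rng.uniform(0, 30, size=(7, 7)), 2)
        flat, paired = tmp_path / "flat.json", tmp_path / "paired.json"
        flat.write_text(json.dumps({"predicted_aligned_error": m.tolist(),
                                    "chain_boundary": 3}))
        r1, r2 = np.meshgrid(np.arange(1, 8), np.arange(1, 8), indexing="ij")
        paired.write_text(json.dumps({
            "residue1": r1.ravel().tolist(), "residue2": r2.ravel().tolist(),
            "distance": m.ravel().tolist(), "chain_boundary": 3,
        }))
        assert np.array_equal(read_pae_matrix(flat).matrix, read_pae_matrix(paired).matrix)

    def test_explicit_boundary_argument_wins(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({"pae": [[1.0] * 4] * 4, "chain_boundary": 1}))
        assert read_pae_matrix(path, chain_boundary=2).chain_boundary == 2

    def test_missing_boundary_rejected(self, tmp_path):
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({"pae": [[1.0] * 4] * 4}))
        with pytest.raises(EvidenceError, match="boundary"):
            read_pae_matrix(path)


class TestInterfacePAE:
    def test_constant_matrix_mean_and_min(self):
        pae = PAEMatrix(np.full((10, 10), 5.0), chain_boundary=6)
        mean, minimum = interface_pae_summary(pae, [6, 7, 8], [0, 1, 2])
        assert mean == 5.0 and minimum == 5.0

    def test_agrees_with_brute_force_block_average(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 30, size=(12, 12))
        pae = PAEMatrix(m, chain_boundary=7)
        motif, rec = [8, 9, 10], [0, 2, 5]
        mean, minimum = interface_pae_summary(pae, motif, rec)
        vals_mr = [m[i, j] for i in motif for j in rec]
        vals_rm = [m[j, i] for i in motif for j in rec]
        expected_mean = (np.mean(vals_mr) + np.mean(vals_rm)) / 2
        assert mean == pytest.approx(expected_mean, rel=1e-12)
        assert minimum == pytest.approx(min(min(vals_mr), min(vals_rm)), rel=1e-12)
        assert min(vals_mr + vals_rm) <= mean <= max(vals_mr + vals_rm)

    def test_indices_on_one_side_rejected(self):
        pae = PAEMatrix(np.ones((10, 10)), chain_boundary=6)
        with pytest.raises(EvidenceError, match="opposite sides"):
            interface_pae_summary(pae, [1, 2], [3, 4])

    def test_empty_index_set_rejected(self):
        pae = PAEMatrix(np.ones((10, 10)), chain_boundary=6)
        with pytest.raises(EvidenceError, match="empty"):
            interface_pae_summary(pae, [], [0])


class TestContacts:
    def test_binder_has_groove_contacts(self, loaded_bundles):
        pred, _ = loaded_bundles["binder"]
        summary = interchain_contacts(pred, DEFAULT_SPA2_GROOVE, MOTIF_START)
        assert summary.groove_contact and summary.n_contact_pairs >= 1
        assert summary.min_distance <= DEFAULT_SPA2_GROOVE.contact_cutoff
        # brute-force re-check of every reported pair
        for rnum, rname, lnum, lname, dist in summary.pairs:
            r_atom = pred.receptor.residue_by_number(rnum).atom(rname)
            l_atom = pred.ligand.residue_by_number(lnum).atom(lname)
            assert np.linalg.norm(r_atom.position - l_atom.position) == pytest.approx(dist, abs=1e-9)
            assert dist <= DEFAULT_SPA2_GROOVE.contact_cutoff

    def test_separated_chains_have_no_contact_but_min_distance(self, loaded_bundles):
        pred, _ = loaded_bundles["separated"]
        summary = interchain_contacts(pred, DEFAULT_SPA2_GROOVE, MOTIF_START)
        assert not summary.groove_contact and summary.n_contact_pairs == 0
        assert summary.min_distance > 50

    def test_missing_groove_residues_reported(self, loaded_bundles):
        pred, _ = loaded_bundles["binder"]
        groove = GrooveDefinition(hydrophobic_patch=(48, 51, 999))
        with pytest.raises(EvidenceError, match="999"):
            interchain_contacts(pred, groove, MOTIF_START)

    def test_rigid_motion_invariance(self, complex_bundles):
        from slimscan.complex_evidence import load_prediction_bundle
        path, _ = complex_bundles["binder"]
        pred = load_prediction_bundle(path, "binder")  # fresh copy, safe to move
        before = interchain_contacts(pred, DEFAULT_SPA2_GROOVE, MOTIF_START)
        rng = np.random.default_rng(9)
        transform_model(pred.model, random_rotation(rng), rng.normal(scale=30, size=3))
        after = interchain_contacts(pred, DEFAULT_SPA2_GROOVE, MOTIF_START)
        assert after.n_contact_pairs == before.n_contact_pairs
        assert after.min_distance == pytest.approx(before.min_distance, abs=1e-6)


class TestHelicity:
    def test_docked_helix_is_helical(self, loaded_bundles):
        pred, _ = loaded_bundles["binder"]
        assert motif_helicity_in_complex(pred, MOTIF_START) is True

    def test_extended_ligand_is_not_helical(self, loaded_bundles):
        pred, _ = loaded_bundles["extended"]
        assert motif_helicity_in_complex(pred, MOTIF_START) is False

    def test_missing_window_not_evaluable(self, loaded_bundles):
        pred, _ = loaded_bundles["binder"]
        assert motif_helicity_in_complex(pred, 1000) is None


class TestOrientation:
    def test_canonical_binder(self, loaded_bundles):
        pred, _ = loaded_bundles["binder"]
        assert classify_orientation(pred, DEFAULT_SPA2_GROOVE, MOTIF_START) == ORIENT_CANONICAL
        # brute-force distances: OH closer to D112 carboxylate than D62's
        oh = pred.ligand.residue_by_number(MOTIF_START + 4).atom("OH").position
        d112 = min(np.linalg.norm(pred.receptor.residue_by_number(112).atom(n).position - oh)
                   for n in ("OD1", "OD2"))
        d62 = min(np.linalg.norm(pred.receptor.residue_by_number(62).atom(n).position - oh)
                  for n in ("OD1", "OD2"))
        assert d112 <= DEFAULT_SPA2_GROOVE.hbond_cutoff < d62

    def test_flipped_binder(self, loaded_bundles):
        pred, _ = loaded_bundles["binder_flipped"]
        assert classify_orientation(pred, DEFAULT_SPA2_GROOVE, MOTIF_START) == ORIENT_FLIPPED

    def test_far_ligand_indeterminate(self, loaded_bundles):
        pred, _ = loaded_bundles["separated"]
        assert classify_orientation(pred, DEFAULT_SPA2_GROOVE, MOTIF_START) == ORIENT_INDETERMINATE

    def test_non_tyrosine_not_applicable(self, loaded_bundles):
        pred, _ = loaded_bundles["binder"]
        plus2 = pred.ligand.residue_by_number(MOTIF_START + 4)
        original = plus2.name3
        plus2.name3 = "PHE"
        try:
            assert classify_orientation(pred, DEFAULT_SPA2_GROOVE, MOTIF_START) == ORIENT_NOT_APPLICABLE
        finally:
            plus2.name3 = original


class TestGatherEvidence:
    def test_binder_evidence_consistent(self, loaded_bundles):
        pred, truth = loaded_bundles["binder"]
        ev = gather_evidence(pred, MOTIF_START)
        assert ev.groove_contact and ev.motif_helical
        assert ev.orientation == ORIENT_CANONICAL
        assert ev.iptm == truth.iptm
        assert ev.interface_pae_min <= ev.interface_pae_mean
        assert ev.interface_pae_mean < 10  # docked: confident interface

    def test_non_binder_high_interface_pae(self, loaded_bundles):
        pred, _ = loaded_bundles["separated"]
        ev = gather_evidence(pred, MOTIF_START)
        assert ev.interface_pae_mean > 15
        assert ev.orientation == ORIENT_INDETERMINATE
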