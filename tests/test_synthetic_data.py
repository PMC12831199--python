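"""synthetic_data: backbone construction, planting, bundles, determinism."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from slimscan.motif_scan import compile_pattern, scan_proteome
from slimscan.secstruct import assign_secondary_structure
from slimscan.structure_io import iterate_proteome
from slimscan.search_pipeline import ss_context_filter
from slimscan.synthetic_data import (
    build_backbone,
    build_mock_shd1,
    generate_localization_table,
    generate_synthetic_complex,
    generate_toy_proteome,
    helix_dihedrals,
)


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestBuildBackbone:
    def test_helix_ca_ca_spacing(self):
        model = build_backbone("A" * 15, helix_dihedrals(15))
        cas = np.array([r.atom("CA").position for r in model.chains[0].residues])
        steps = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        assert np.allclose(steps, 3.80, atol=0.02)

    def test_helix_o_to_n4_within_hbond_range(self):
        model = build_backbone("A" * 15, helix_dihedrals(15))
        residues = model.chains[0].residues
        for i in range(len(residues) - 4):
            o = residues[i].atom("O").position
            n = residues[i + 4].atom("N").position
            assert np.linalg.norm(o - n) < 3.5

    def test_cbeta_placed_for_non_glycine_only(self):
        model = build_backbone("AGA", helix_dihedrals(3))
        residues = model.chains[0].residues
        assert residues[0].atom("CB") is not None
        assert residues[1].atom("CB") is None

    def test_single_residue_chain(self):
        model = build_backbone("A", [(0.0, 0.0)])
        assert len(model.chains[0].residues) == 1
        assert model.chains[0].residues[0].has_backbone()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dihedral"):
            build_backbone("AAA", helix_dihedrals(2))

    def test_all_coordinates_finite(self):
        model = build_backbone("ACDEFHIKLMNQRSTVWY", helix_dihedrals(18),
                               sidechain_stubs=True)
        assert np.all(np.isfinite(model.all_coordinates()))


class TestMockReceptor:
    def test_groove_definition_residues_resolve(self):
        receptor = build_mock_shd1()
        for num in (48, 51, 59, 98, 101, 109):
            res = receptor.residue_by_number(num)
            assert res is not None and res.name3 == "LEU"
        for num in (62, 112):
            res = receptor.residue_by_number(num)
            assert res.name3 == "ASP"
            assert res.atom("OD1") is not None and res.atom("OD2") is not None
        assert receptor.residue_by_number(97).name3 == "LYS"

    def test_receptor_is_deterministic(self):
        r1, r2 = build_mock_shd1(), build_mock_shd1()
        for a1, a2 in zip(
            (a for r in r1.residues for a in r.atoms),
            (a for r in r2.residues for a in r.atoms),
        ):
            assert np.array_equal(a1.position, a2.position)


class TestToyProteome:
    def test_scan_recovers_exactly_the_truth_set(self, tmp_path):
        truth = generate_toy_proteome(
            tmp_path, seed=7, plantings=[("helix", 10)], n_extra=40,
        )
        assert truth.n_proteins == 50 and len(truth.planted) == 10
        pattern = compile_pattern(truth.pattern)
        result = scan_proteome(iterate_proteome(tmp_path), pattern)
        found = {(m.model_id, m.start) for m in result.matches}
        expected = {(p.protein_id, p.start) for p in truth.planted} | {
            (p.protein_id, p.start) for p in truth.accidental
        }
        assert found == expected

    def test_same_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_toy_proteome(a, seed=3, plantings=[("helix", 2), ("coil", 2)])
        generate_toy_proteome(b, seed=3, plantings=[("helix", 2), ("coil", 2)])
        assert _tree_digest(a) == _tree_digest(b)

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_toy_proteome(a, seed=3, plantings=[("helix", 2)], n_extra=2)
        generate_toy_proteome(b, seed=4, plantings=[("helix", 2)], n_extra=2)
        assert _tree_digest(a) != _tree_digest(b)

    @pytest.mark.parametrize("context,expected_pass", [
        ("helix", True), ("coil", True), ("strand", False),
    ])
    def test_planted_context_drives_ss_filter(self, tmp_path, context, expected_pass):
        truth = generate_toy_proteome(
            tmp_path / context, seed=13, plantings=[(context, 3)], n_extra=0,
        )
        for planted, model in zip(truth.planted, iterate_proteome(tmp_path / context)):
            ann = assign_secondary_structure(model)
            labels = ann.window(model.chains[0], planted.start)
            assert ss_context_filter(labels) is expected_pass, (planted, labels)


class TestLocalizationTable:
    def test_fraction_one_all_cytosolic(self, tmp_path):
        ids = [f"P{i}" for i in range(10)]
        realized = generate_localization_table(tmp_path / "l.tsv", ids, 1.0, seed=0)
        assert all(realized.values())

    def test_fraction_zero_none_cytosolic(self, tmp_path):
        ids = [f"P{i}" for i in range(10)]
        realized = generate_localization_table(tmp_path / "l.tsv", ids, 0.0, seed=0)
        assert not any(realized.values())

    def test_fixed_seed_reproducible(self, tmp_path):
        ids = [f"P{i}" for i in range(30)]
        r1 = generate_localization_table(tmp_path / "a.tsv", ids, 0.5, seed=8)
        r2 = generate_localization_table(tmp_path / "b.tsv", ids, 0.5, seed=8)
        assert r1 == r2
        assert (tmp_path / "a.tsv").read_text() == (tmp_path / "b.tsv").read_text()

    def test_invalid_fraction_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_localization_table(tmp_path / "l.tsv", ["P1"], 1.5, seed=0)


class TestSyntheticComplex:
    def test_binder_with_failure_stage_is_contradictory(self, tmp_path):
        with pytest.raises(ValueError, match="failure stage"):
            generate_synthetic_complex(tmp_path, "x", binder=True,
                                       failure_stage=5, seed=0)

    def test_stage5_failure_has_good_geometry_low_iptm(self, loaded_bundles):
        pred, truth = loaded_bundles["low_iptm"]
        from slimscan.complex_evidence import gather_evidence
        ev = gather_evidence(pred, truth.motif_start)
        assert ev.groove_contact and ev.motif_helical
        assert truth.iptm < 0.60

    def test_binder_iptm_at_or_above_reference(self, loaded_bundles):
        for name in ("binder", "binder_flipped"):
            _, truth = loaded_bundles[name]
            assert truth.iptm >= 0.60

    def test_same_seed_identical_bundle(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_synthetic_complex(a, "x", binder=True, seed=5)
        generate_synthetic_complex(b, "x", binder=True, seed=5)
        assert _tree_digest(a) == _tree_digest(b)


class TestFunnelBenchmark:
    def test_expected_counts_reflect_roster(self, benchmark):
        _, truth = benchmark
        counts = truth.expected_counts()
        assert counts["stage1"] == 18
        assert counts["stage1"] >= counts["stage2"] >= counts["stage3"]
        assert counts["stage3"] >= counts["stage4"] >= counts["stage5"]
        assert counts["stage5"] == len(truth.binder_ids)

    def test_truth_json_round_trip(self, benchmark):
        out, truth = benchmark
        from slimscan.synthetic_data import SyntheticTruth
        loaded = SyntheticTruth.from_json(out / "truth.json")
        assert loaded.expected_counts() == truth.expected_counts()
        assert loaded.reference_id == truth.reference_id
        assert loaded.failure_stage == truth.failure_stage
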