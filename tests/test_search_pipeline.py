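"""search_pipeline: stage predicates, funnel orchestration, reporting."""

import json

import pytest

from slimscan.search_pipeline import (
    Candidate,
    LocalizationTable,
    PipelineConfig,
    PipelineError,
    iptm_filter,
    localization_filter,
    read_report_counts,
    run_search,
    ss_context_filter,
    write_report,
)


def _cand(pid, iptm=None):
    c = Candidate(protein_id=pid)
    c.iptm = iptm
    return c


class TestSSContextFilter:
    @pytest.mark.parametrize("labels,keep", [
        ("HHHHH", True),    # fully helical
        ("CCCCC", True),    # fully loop
        ("HHCHH", True),    # mixed helix/loop
        ("HHEHH", False),   # any strand residue discards
        ("EEEEE", False),
        (None, False),      # unannotated
        ("HHH", False),     # wrong width
    ])
    def test_rule(self, labels, keep):
        assert ss_context_filter(labels) is keep


class TestLocalizationFilter:
    @pytest.fixture
    def table(self, tmp_path):
        p = tmp_path / "loc.tsv"
        p.write_text(
            "protein_id\tlocalization\n"
            "P1\tcytosol\n"
            "P2\tnucleus\n"
            "P3\tnucleus,cytoplasm\n"
        )
        return LocalizationTable.from_tsv(p)

    def test_cytosolic_kept(self, table):
        kept = localization_filter([_cand("P1")], table)
        assert [c.protein_id for c in kept] == ["P1"]

    def test_nuclear_dropped_with_reason(self, table):
        cand = _cand("P2")
        assert localization_filter([cand], table) == []
        assert cand.exclusion_stage == 3 and "non-cytosolic" in cand.exclusion_reason

    def test_mixed_labels_count_as_cytosolic(self, table):
        assert localization_filter([_cand("P3")], table)

    def test_absent_protein_kept_and_flagged_by_default(self, table):
        cand = _cand("P9")
        kept = localization_filter([cand], table)
        assert kept and "unknown-localization" in cand.flags

    def test_absent_protein_dropped_in_strict_mode(self, table):
        assert localization_filter([_cand("P9")], table, unknown_policy="drop") == []

    def test_lookup_case_insensitive(self, table):
        assert table.is_cytosolic("p1") is True and table.is_cytosolic("P9") is None


class TestIptmFilter:
    def test_equal_to_reference_survives(self):
        kept = iptm_filter([_cand("P1", iptm=0.62)], reference_iptm=0.62)
        assert len(kept) == 1

    def test_below_reference_dropped(self):
        assert iptm_filter([_cand("P1", iptm=0.61)], reference_iptm=0.62) == []

    def test_reference_candidate_always_survives_itself(self):
        ref = _cand("REF", iptm=0.60)
        assert iptm_filter([ref], reference_iptm=0.60) == [ref]

    def test_missing_reference_is_config_error(self):
        with pytest.raises(PipelineError):
            iptm_filter([_cand("P1", iptm=0.9)], reference_iptm=None)


class TestRunSearch:
    def test_funnel_counts_match_designed_truth(self, benchmark_report):
        report, truth = benchmark_report
        assert report.counts() == truth.expected_counts()

    def test_survivor_sets_equal_truth_at_every_stage(self, benchmark_report):
        report, truth = benchmark_report
        assert report.survivors(1) == set(truth.failure_stage)
        for stage in (2, 3, 4, 5):
            assert report.survivors(stage) == truth.expected_survivors(stage)

    def test_funnel_monotonic_and_nested(self, benchmark_report):
        report, _ = benchmark_report
        report.validate_monotonic()
        counts = [s.count for s in report.stages]
        assert counts == sorted(counts, reverse=True)

    def test_stage5_precision_and_recall_are_one(self, benchmark_report):
        report, truth = benchmark_report
        predicted = report.survivors(5)
        actual = truth.binder_ids
        assert predicted == actual  # precision = recall = 1.0
        tp = len(predicted & actual)
        assert tp / len(predicted) == 1.0 and tp / len(actual) == 1.0

    def test_skipped_stage_copies_survivors_forward(self, benchmark):
        out, truth = benchmark
        config = PipelineConfig(
            proteome_source=out / "proteome", pattern=truth.pattern,
            localization_table=None, bundle_dir=None,
        )
        report = run_search(config)
        assert report.survivors(3) == report.survivors(2)
        assert [s.skipped for s in report.stages] == [False, False, True, True, True]

    def test_rerun_is_deterministic(self, benchmark, benchmark_report):
        out, truth = benchmark
        report1, _ = benchmark_report
        config = PipelineConfig(
            proteome_source=out / "proteome", pattern=truth.pattern,
            localization_table=out / "localization.tsv",
            bundle_dir=out / "bundles", reference_id=truth.reference_id,
        )
        report2 = run_search(config)
        assert report1.counts() == report2.counts()
        for stage in (1, 2, 3, 4, 5):
            assert report1.survivors(stage) == report2.survivors(stage)

    def test_exclusion_reasons_recorded(self, benchmark_report):
        report, truth = benchmark_report
        for pid, stage in truth.failure_stage.items():
            cand = report.candidates[pid]
            if stage is None:
                assert cand.exclusion_stage is None
            else:
                assert cand.exclusion_stage == stage, pid

    def test_reference_iptm_resolved_from_bundle(self, benchmark_report):
        report, truth = benchmark_report
        assert report.provenance["reference_iptm"] == pytest.approx(truth.reference_iptm)


class TestReports:
    def test_json_round_trip_preserves_counts(self, benchmark_report, tmp_path):
        report, _ = benchmark_report
        path = write_report(report, tmp_path / "report.json", "json")
        assert read_report_counts(path) == report.counts()

    def test_tsv_has_one_row_per_stage(self, benchmark_report, tmp_path):
        report, _ = benchmark_report
        path = write_report(report, tmp_path / "funnel.tsv", "tsv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 5

    def test_experimental_validation_column_pending(self, benchmark_report, tmp_path):
        report, _ = benchmark_report
        path = write_report(report, tmp_path / "report.json", "json")
        payload = json.loads(path.read_text())
        assert all(c["experimental_validation"] == "pending"
                   for c in payload["candidates"].values())

    def test_yaml_config_round_trip(self, benchmark, tmp_path):
        out, truth = benchmark
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            f"proteome_source: {out/'proteome'}\n"
            f'pattern: "{truth.pattern}"\n'
            f"localization_table: {out/'localization.tsv'}\n"
            f"bundle_dir: {out/'bundles'}\n"
            f"reference_id: {truth.reference_id}\n"
        )
        config = PipelineConfig.from_yaml(cfg_path)
        assert run_search(config).counts() == truth.expected_counts()
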