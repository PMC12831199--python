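"""Shared fixtures: one funnel benchmark and a set of complex bundles,
generated once per session from fixed seeds."""

from __future__ import annotations

import pytest

from slimscan.complex_evidence import load_prediction_bundle
from slimscan.search_pipeline import PipelineConfig, run_search
from slimscan.synthetic_data import (
    generate_funnel_benchmark,
    generate_synthetic_complex,
)

BENCHMARK_SEED = 11


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """Funnel benchmark directory plus its ground truth."""
    out = tmp_path_factory.mktemp("bench")
    truth = generate_funnel_benchmark(out, seed=BENCHMARK_SEED)
    return out, truth


@pytest.fixture(scope="session")
def benchmark_report(benchmark):
    out, truth = benchmark
    config = PipelineConfig(
        proteome_source=out / "proteome",
        pattern=truth.pattern,
        localization_table=out / "localization.tsv",
        bundle_dir=out / "bundles",
        reference_id=truth.reference_id,
    )
    return run_search(config), truth


@pytest.fixture(scope="session")
def complex_bundles(tmp_path_factory):
    """One prediction bundle per designed behaviour, with its truth."""
    root = tmp_path_factory.mktemp("bundles")
    specs = {
        "binder": dict(binder=True, orientation="canonical_D112", seed=3),
        "binder_flipped": dict(binder=True, orientation="flipped_D62", seed=4),
        "separated": dict(binder=False, failure_stage=4, seed=10),
        "extended": dict(binder=False, failure_stage=4, seed=11),
        "low_iptm": dict(binder=False, failure_stage=5, seed=12),
    }
    out = {}
    for name, kwargs in specs.items():
        truth = generate_synthetic_complex(root / name, name, **kwargs)
        out[name] = (root / name, truth)
    return out


@pytest.fixture(scope="session")
def loaded_bundles(complex_bundles):
    return {
        name: (load_prediction_bundle(path, name), truth)
        for name, (path, truth) in complex_bundles.items()
    }
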