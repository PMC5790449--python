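"""Shared fixtures.

``default_run`` executes the full default scenario (4 specimens x 12 samples,
50k reads/sample) once per session; the acceptance tests share its output.
Everything else is small and fast.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from rnacensus.pipeline import PipelineConfig, run_pipeline
from rnacensus.simulate import (
    SimulationConfig,
    build_reference,
    simulate_cohort,
    simulate_truth_counts,
)

SMALL_SAMPLES = {"plasma": 4, "stool": 4, "urine": 4, "cervical": 4}


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=7, depth=2000, n_samples_per_specimen=dict(SMALL_SAMPLES))


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_reference(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_bundle):
    return simulate_truth_counts(small_config, small_bundle)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_bundle):
    return simulate_cohort(small_config, small_bundle)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> dict:
    """Full default-scenario pipeline run (the 10-minute acceptance budget)."""
    out_dir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(out_dir=str(out_dir), seed=11, write_intermediate=False)
    manifest = run_pipeline(config)
    bundle = build_reference(config.simulation)
    truth = simulate_truth_counts(config.simulation, bundle)
    return {
        "out": Path(out_dir),
        "manifest": manifest,
        "config": config,
        "bundle": bundle,
        "truth": truth,
    }
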