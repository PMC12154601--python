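"""Shared fixtures: one default synthetic study and one full pipeline run,
both session-scoped so the expensive stages execute once."""

import pytest

from coelute.pipeline import PipelineConfig, SyntheticConfig, run_pipeline
from coelute.synthetic import (SimulationParams, correlation_network,
                               generate_truth, simulate_all_experiments)


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_params):
    return generate_truth(default_params)


@pytest.fixture(scope="session")
def default_experiments(default_truth, default_params):
    return simulate_all_experiments(default_truth, default_params)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """Full default pipeline on the 200-orthogroup synthetic study."""
    cfg = PipelineConfig(synthetic=SyntheticConfig(), seed=1)
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(cfg, out)


@pytest.fixture(scope="session")
def null_network():
    """~500-node weighted co-elution network for seed-propagation nulls."""
    params = SimulationParams(n_complexes=90, n_monomers=100, seed=11)
    return correlation_network(params)
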