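"""Shared fixtures: a design, a simulated dataset and one full pipeline run."""

import numpy as np
import pytest
from hypothesis import settings

from ecoislands.design import build_design
from ecoislands.pipeline import RunConfig, run_pipeline
from ecoislands.synthesis import SimulationParams, simulate_dataset

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design():
    return build_design(seed=1)


@pytest.fixture(scope="session")
def dataset(design):
    return simulate_dataset(design, SimulationParams(seed=3))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One complete seeded pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("run") / "r1"
    cfg = RunConfig(seed=1, out_dir=str(out))
    run_pipeline(cfg)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
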