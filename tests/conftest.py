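import numpy as np
import pytest

from epichrom.config import PipelineConfig
from epichrom.simulate import simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic dataset shared across tests (seed 0)."""
    return simulate_all(PipelineConfig(seed=0).simulation)


@pytest.fixture(scope="session")
def default_pipeline_result():
    """One full default pipeline run shared across tests (seed 0)."""
    from epichrom.pipeline import run_pipeline

    return run_pipeline(PipelineConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
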