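import numpy as np
import pytest

from lncdyn.pipeline import PipelineConfig, PipelineInputs, run_pipeline
from lncdyn.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim1():
    """Default synthetic dataset at a fixed seed, shared across the suite."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline1(sim1):
    """One full pipeline run on the shared dataset (the expensive fixture)."""
    return run_pipeline(PipelineInputs.from_simulation(sim1), PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
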