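import numpy as np
import pytest

from holdase import pipeline, simulate


@pytest.fixture(scope="session")
def default_truth():
    return simulate.SimulationTruth(seed=7)


@pytest.fixture(scope="session")
def default_config():
    return pipeline.PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def panel_tables(default_truth, default_config):
    """One simulated full design (12 mutants + WT*, 2 conditions, 3 reps),
    shared across tests that only read it."""
    return pipeline.run_simulate(default_config, truth=default_truth, replicates=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
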