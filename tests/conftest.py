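import numpy as np
import pytest

from gatewalk import ModelConfig, simulate
from gatewalk.event_detection import extract_dwells


@pytest.fixture(scope="session")
def m1_cfg():
    return ModelConfig.model1()


@pytest.fixture(scope="session")
def m2_cfg():
    return ModelConfig.model2()


@pytest.fixture(scope="session")
def m1_trace():
    """One mid-sized symmetric-drift Model 1 run, shared across tests."""
    return simulate(ModelConfig.model1(), 1_000_000, seed=11)


@pytest.fixture(scope="session")
def m1_dwells(m1_trace):
    return extract_dwells(m1_trace)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
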