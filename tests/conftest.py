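import numpy as np
import pytest

from stopmark.behavior import BehavioralDataset
from stopmark.task import RaceModelParams, TaskConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One 450-trial run with the default generator parameters."""
    return simulate_session(RaceModelParams(seed=11))


@pytest.fixture(scope="session")
def default_dataset(default_session):
    return BehavioralDataset(list(default_session))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
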