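import numpy as np
import pytest

from smrloop import EegGenConfig, TrialSchedule, generate_eeg


@pytest.fixture(scope="session")
def schedule10():
    return TrialSchedule.standard(10)


@pytest.fixture(scope="session")
def eeg_block(schedule10):
    """One moderate-depth EEG evaluation block shared across tests."""
    return generate_eeg(EegGenConfig(erd_depth=0.4, seed=12345), schedule10)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
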