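import dataclasses

import numpy as np
import pytest

import bisnn
from bisnn import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    """A short session: 4 trials, default channel/target layout."""
    return sd.SynthConfig(n_trials=4)


@pytest.fixture(scope="session")
def small_session(small_config):
    return sd.generate_session(small_config, seed=101)


@pytest.fixture(scope="session")
def small_test_session(small_config):
    return sd.generate_session(dataclasses.replace(small_config, n_trials=3), seed=202)


@pytest.fixture(scope="session")
def small_model(small_session):
    s = small_session
    return bisnn.fit(
        s.inputs, s.targets, s.montage, s.trial_windows, bisnn.DecoderConfig(), seed=7
    )


@pytest.fixture(scope="session")
def small_prediction(small_model, small_test_session):
    return bisnn.predict_stream(small_model, small_test_session.inputs, mode="batch")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
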