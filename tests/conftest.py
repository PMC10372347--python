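import numpy as np
import pytest

from wtanet import StimulusProtocol, TrialConfig


@pytest.fixture(scope="session")
def short_trial_cfg():
    """A short but otherwise default trial: 1 s with an early stimulus."""
    return TrialConfig(
        total_duration=1000.0,
        stimulus=StimulusProtocol(onset=200.0, duration=500.0),
        persistence_window=300.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
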