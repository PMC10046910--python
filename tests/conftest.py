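import numpy as np
import pytest

from kcsfcnet.model import KCSFCnet
from kcsfcnet.synthetic import Coupling, SyntheticSpec, generate_subject


@pytest.fixture(scope="session")
def small_planted():
    """Compact planted-coupling subject: 8 channels, 40 trials, snr 2."""
    spec = SyntheticSpec(
        n_trials=40, n_channels=8, fs=128.0, duration=2.0,
        couplings=(Coupling((0, 1), 8.0, 13.0, 1), Coupling((2, 3), 18.0, 24.0, 0)),
        snr=2.0, seed=7,
    )
    return generate_subject(spec)


@pytest.fixture(scope="session")
def fitted_small(small_planted):
    """A trained compact model, shared by the model-behaviour tests."""
    model = KCSFCnet(n_filters=2, kernel_length=32, n_epochs=200, random_state=0)
    model.fit(small_planted.data, small_planted.labels)
    return model


@pytest.fixture
def tiny_trials():
    """Eight 4-channel trials for cheap analytic checks."""
    spec = SyntheticSpec(
        n_trials=8, n_channels=4, fs=64.0, duration=0.5,
        couplings=(Coupling((0, 1), 8.0, 13.0, 1),), snr=1.0, seed=3,
    )
    return generate_subject(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
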