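import logging

import numpy as np
import pytest

import footkinetics as fk

# the Nyquist-clipping warning for the 50 Hz kinetic filter is expected noise
logging.getLogger("footkinetics.curve_stats").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noiseless_model():
    """Default gait model with sensor noise switched off."""
    return fk.default_model(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_model):
    """One noiseless trial with its continuous-field ground truth."""
    trial, gt = fk.simulate_trial(noiseless_model)
    return trial, gt


@pytest.fixture(scope="session")
def fine_grid_trial():
    """Noiseless trial sampled on a fine (5 mm) platform grid, with truth."""
    model = fk.default_model(noise_sd=0.0, platform_pitch=0.005)
    trial, gt = fk.simulate_trial(model)
    return model, trial, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
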