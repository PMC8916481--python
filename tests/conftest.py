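import logging

import numpy as np
import pytest

from mmrbss import OddballDesign, SourceModel, simulate_recording

# joint-diagonalization non-convergence on noisy data is expected and logged
logging.getLogger("mmrbss").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down oddball design for fast tests (timing as the study:
    500 ms SOA, 20% deviants)."""
    return OddballDesign(min_deviants=20, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_design):
    """16-channel recording at SNR 5 with ground truth."""
    model = SourceModel.default(n_channels=16, design=small_design, snr=5.0)
    return simulate_recording(small_design, model)


@pytest.fixture(scope="session")
def noiseless_sim(small_design):
    """Same sources, all noise amplitudes zero: x = A s exactly."""
    model = SourceModel.default(n_channels=16, design=small_design, snr=5.0,
                                sensor_noise_sd=0.0, pink_amplitude=0.0,
                                alpha_amplitude=0.0)
    return simulate_recording(small_design, model)
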