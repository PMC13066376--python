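import numpy as np
import pytest

from meetsemg import (
    SynthConfig,
    bandpass_filter,
    featurize,
    generate_recording,
    notch_filter,
    segment_windows,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Six-gesture subject with short 4 s blocks, for fast unit tests."""
    return SynthConfig(n_subjects=1, gesture_duration_s=4.0, seed=7)


@pytest.fixture(scope="session")
def high_snr_config():
    """Strong bursts, weak contamination: class signatures dominate."""
    return SynthConfig(
        n_subjects=1,
        gesture_duration_s=8.0,
        noise_sd=0.005,
        powerline_amplitude=0.02,
        drift_amplitude=0.01,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate_recording(small_config, 0)


@pytest.fixture(scope="session")
def high_snr_features(high_snr_config):
    rec = generate_recording(high_snr_config, 0)
    rec = notch_filter(bandpass_filter(rec))
    return featurize(segment_windows(rec))
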