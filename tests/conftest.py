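import numpy as np
import pytest

from tebc.preprocess import build_filter_bank
from tebc.synthetic import SimConfig, simulate_experiment

FS = 500.0
EPOCH = (-0.8, 0.9)


@pytest.fixture(scope="session")
def small_bank():
    """12 log-spaced bands, 4-60 Hz at 500 Hz."""
    return build_filter_bank(4.0, 60.0, 12, fs=FS)


@pytest.fixture(scope="session")
def nine_hz_bank():
    """Half-octave bank anchored at 9 Hz (9 ... 72 Hz)."""
    return build_filter_bank(freqs=9.0 * np.sqrt(2) ** np.arange(7), fs=FS)


@pytest.fixture(scope="session")
def plain_experiment():
    """One rat, two sessions of pure-noise trials plus EMG blinks."""
    cfg = SimConfig(n_rats=1, n_sessions=2, n_trials=20, fs=FS, epoch=EPOCH,
                    hr_curve=(0.3, 0.7))
    sessions, gt = simulate_experiment(cfg, seed=11)
    return cfg, sessions, gt
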