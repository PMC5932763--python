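import numpy as np
import pytest

from hrvtf import synth_ecg
from hrvtf.tf import ConceFTConfig


@pytest.fixture(scope="session")
def clean_toy():
    """60 s noiseless, jitter-free toy ECG at 500 Hz."""
    return synth_ecg(duration_s=60.0, fs=500.0, mean_rr=800.0, rr_jitter=0.0,
                     ectopic_rate=0.0, seed=0)


@pytest.fixture(scope="session")
def ectopic_toy():
    """15 min toy ECG with jitter and 10% ectopic beats."""
    return synth_ecg(duration_s=900.0, fs=500.0, mean_rr=800.0, rr_jitter=25.0,
                     ectopic_rate=0.10, seed=3)


@pytest.fixture()
def small_cfg():
    """Light transform configuration for fast unit tests."""
    return ConceFTConfig(J=1, N=1, half_width=2.0, freq_lo=5.0, freq_hi=15.0,
                         n_freq_bins=201, hop=10, seed=0)


def tone(freq_hz: float, duration_s: float = 60.0, fs: float = 100.0) -> np.ndarray:
    t = np.arange(0.0, duration_s, 1.0 / fs)
    return np.cos(2 * np.pi * freq_hz * t)
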