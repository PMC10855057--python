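import numpy as np
import pytest
from scipy.signal import periodogram

from respyre import SyntheticConfig, generate_ppg, highpass_vlf, lowpass_ppg


def dominant_frequency(samples: np.ndarray, fs: float) -> tuple[float, float]:
    """(dominant frequency, bin width) of a de-meaned periodogram."""
    x = np.asarray(samples, dtype=float)
    freqs, power = periodogram(x - x.mean(), fs=fs)
    return float(freqs[np.argmax(power)]), float(freqs[1] - freqs[0])


@pytest.fixture(scope="session")
def clean_ppg():
    """60 s noise-free PPG, HR 75, RR 15, all modulation depths 0.1."""
    cfg = SyntheticConfig(duration_s=60.0, heart_rate=75.0, resp_rate=15.0, seed=1)
    return generate_ppg(cfg)


@pytest.fixture(scope="session")
def noisy_filtered_ppg():
    """Filtered 60 s PPG with 5% noise: the classical chain's input."""
    cfg = SyntheticConfig(duration_s=60.0, heart_rate=75.0, resp_rate=15.0,
                          noise_sd=0.05, seed=2)
    sig, ann = generate_ppg(cfg)
    return highpass_vlf(lowpass_ppg(sig)), ann
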