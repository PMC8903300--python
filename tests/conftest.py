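import numpy as np
import pandas as pd
import pytest

from soilscape.acoustics import Recording
from soilscape.synthdata import SoundscapeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20190615)


@pytest.fixture
def small_soundscape():
    """Reduced-rate soundscape config for fast audio tests."""
    return SoundscapeConfig(rate=8000, clip_seconds=3.2768,
                            interval_minutes=10, noise_sigma=0.012, seed=7)


@pytest.fixture
def noise_recording(rng):
    """A 50-kHz Gaussian-noise clip shaped like a field recording."""
    n = 2020 * 512
    return Recording(samples=rng.normal(0.0, 0.02, n), rate=50_000,
                     start_time=pd.Timestamp("2019-06-20 12:00"),
                     sensor_id="B1")


def aci_bruteforce(intensity: np.ndarray, frames_per_clump: int) -> float:
    """Independent oracle: direct evaluation of the three printed formulas.

    d_k = |I_k - I_{k+1}|; D = sum d_k; ratio = D / sum I_k, per band and
    clump; the index is the plain average of all ratios.
    """
    n_bands, n_frames = intensity.shape
    n_clumps = n_frames // frames_per_clump
    ratios = []
    for b in range(n_bands):
        for c in range(n_clumps):
            seg = intensity[b, c * frames_per_clump:(c + 1) * frames_per_clump]
            d = sum(abs(seg[j] - seg[j + 1]) for j in range(len(seg) - 1))
            s = sum(seg)
            ratios.append(d / s if s > 0 else 0.0)
    return float(np.mean(ratios))
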