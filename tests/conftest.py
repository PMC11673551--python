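import numpy as np
import pytest

from glycotrace.types import Spectrum


def gaussians(x, peaks):
    """Sum of (center, height, sigma) Gaussians evaluated on x."""
    y = np.zeros_like(x, dtype=float)
    for c, h, s in peaks:
        y += h * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def make_spectrum(peaks, step=0.05, region=(150.0, 350.0),
                  stage="baseline-corrected", sample_id=""):
    n = int(round((region[1] - region[0]) / step)) + 1
    x = region[0] + step * np.arange(n)
    return Spectrum(x, gaussians(x, peaks), stage=stage, sample_id=sample_id)


@pytest.fixture
def region_grid():
    x = 150.0 + 0.05 * np.arange(4001)
    return x


@pytest.fixture
def spectrum_factory():
    return make_spectrum
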