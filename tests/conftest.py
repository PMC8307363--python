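import numpy as np
import pytest

from cisim import (
    AudioSignal,
    default_band_edges,
    design_fir_bank,
    design_iir_bank,
)

FS = 22050


@pytest.fixture(scope="session")
def fir_bank():
    return design_fir_bank()


@pytest.fixture(scope="session")
def iir_bank():
    return design_iir_bank()


@pytest.fixture(scope="session")
def edges():
    return default_band_edges()


@pytest.fixture
def white_noise():
    rng = np.random.default_rng(42)
    return AudioSignal(samples=rng.standard_normal(2**15), sample_rate=FS)


def tone(freq: float, duration: float = 0.5, fs: float = FS, amplitude: float = 1.0):
    t = np.arange(round(duration * fs)) / fs
    return AudioSignal(samples=amplitude * np.sin(2 * np.pi * freq * t), sample_rate=fs)
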