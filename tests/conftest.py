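import numpy as np
import pytest

from ctgbemd.bemd import BivariateSignal, SiftConfig, bemd

FS = 4.0


def tone(freq, duration_s, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t + phase)


def rotation(freq, duration_s, fs=FS, amp=1.0):
    """Constant-modulus complex rotation amp * e^{j 2 pi f t}."""
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.exp(2j * np.pi * freq * t)


def fft_peak_hz(x, fs=FS):
    """Frequency (Hz) of the dominant rFFT magnitude bin."""
    x = np.asarray(x, float)
    spec = np.abs(np.fft.rfft(x - x.mean()))
    return np.fft.rfftfreq(x.size, 1.0 / fs)[int(np.argmax(spec))]


def interior(x, frac=0.05):
    k = int(len(x) * frac)
    return x[k: len(x) - k]


@pytest.fixture(scope="session")
def two_tone_signal():
    """Lagged two-tone bivariate signal (0.25 Hz and 0.02 Hz shared tones)."""
    t = np.arange(int(600 * FS)) / FS
    fhr = np.cos(2 * np.pi * 0.25 * t) + 1.5 * np.cos(2 * np.pi * 0.02 * t)
    uc = 0.6 * np.cos(2 * np.pi * 0.25 * t + np.pi / 3) \
        + 1.0 * np.cos(2 * np.pi * 0.02 * t + np.pi / 2)
    return BivariateSignal.from_channels(fhr, uc, FS)


@pytest.fixture(scope="session")
def two_tone_imfs(two_tone_signal):
    return bemd(two_tone_signal, SiftConfig())
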