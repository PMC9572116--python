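import numpy as np
import pytest

from radarvitals import (
    ChestMotionModel,
    ImpairmentModel,
    RadarConfig,
    simulate_cube,
)

FS_SLOW = 20.0  # frame rate of the default configuration (Hz)


@pytest.fixture
def config():
    return RadarConfig()


@pytest.fixture
def clean_motion():
    """Breathing + heartbeat, no harmonics, for analytic checks."""
    return ChestMotionModel(
        R0=1.0,
        breath_amp=1e-3,
        breath_freq=0.3,
        heart_amp=1e-4,
        heart_freq=1.2,
        harmonic_coeffs=(),
    )


@pytest.fixture
def clean_cube(config, clean_motion):
    """Impairment-free cube: the analytic reference for demodulation."""
    return simulate_cube(config, clean_motion, ImpairmentModel())


def two_tone(n=255, fs=FS_SLOW, a1=0.3, f1=0.3, a2=0.12, f2=1.2):
    """Phase-difference-like two-tone test signal."""
    t = np.arange(n) / fs
    return a1 * np.sin(2 * np.pi * f1 * t) + a2 * np.sin(2 * np.pi * f2 * t)


def spectral_snr_db(x, fs, f_target):
    """Three-line spectral SNR (dB) at the line nearest f_target.

    Kept deliberately independent of the package's snr_metric: straight
    rFFT energies, used as the oracle in denoising-efficacy checks.
    """
    e = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    p = int(np.argmin(np.abs(freqs - f_target)))
    p = p - 1 + int(np.argmax(e[p - 1:p + 2]))
    e3 = e[p - 1:p + 2].sum()
    return 10 * np.log10(e3 / (e.sum() - e3))
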