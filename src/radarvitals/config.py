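"""Radar waveform / framing configuration.

An FMCW radar transmits linear frequency sweeps (chirps).  The mixer output
(beat signal) of a chirp reflected by a target at range ``R0`` is a complex
tone whose frequency ``f_b = 2*K*R0/c`` encodes range and whose phase
``4*pi*R0/lambda`` encodes sub-wavelength displacement.  One chirp is
transmitted per frame; the across-frame ("slow-time") phase at the target's
range bin therefore samples chest displacement at the frame rate ``1/Ts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

C_LIGHT = 299_792_458.0
"""Speed of light (m/s)."""


@dataclass(frozen=True)
class RadarConfig:
    """Chirp and frame timing of the FMCW front end.

    Parameters
    ----------
    fc : float
        Chirp start frequency (Hz).  Default 77 GHz.
    Tc : float
        Chirp duration (s).
    slope : float
        Chirp slope K (Hz/s).
    Fs : float
        ADC sampling rate (samples/s) on fast time.
    Ts : float
        Frame period (s); the slow-time sampling interval.
    n_samples : int
        Fast-time samples recorded per chirp.
    n_frames : int
        Number of frames (slow-time length).
    """

    fc: float = 77e9
    Tc: float = 50e-6
    slope: float = 80e12  # 80 MHz/us
    Fs: float = 6.4e6
    Ts: float = 50e-3
    n_samples: int = 256
    n_frames: int = 256

    def __post_init__(self) -> None:
        for name in ("fc", "Tc", "slope", "Fs", "Ts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RadarConfig.{name} must be positive")
        if self.n_samples < 1 or self.n_frames < 1:
            raise ValueError("n_samples and n_frames must be >= 1")
        if self.n_samples / self.Fs > self.Tc * (1 + 1e-12):
            raise ValueError(
                f"ADC window n_samples/Fs = {self.n_samples / self.Fs:.3g} s "
                f"exceeds chirp duration Tc = {self.Tc:.3g} s"
            )

    @property
    def lambda_max(self) -> float:
        """Wavelength c/fc at the chirp start frequency (m)."""
        return C_LIGHT / self.fc

    @property
    def bandwidth(self) -> float:
        """Full sweep bandwidth slope*Tc (Hz)."""
        return self.slope * self.Tc

    @property
    def effective_bandwidth(self) -> float:
        """Bandwidth actually sampled by the ADC, slope*n_samples/Fs (Hz)."""
        return self.slope * self.n_samples / self.Fs

    @property
    def fs_slow(self) -> float:
        """Slow-time (frame) sampling rate 1/Ts (Hz)."""
        return 1.0 / self.Ts

    @property
    def duration(self) -> float:
        """Observation duration n_frames*Ts (s)."""
        return self.n_frames * self.Ts

    @property
    def max_range(self) -> float:
        """Largest unambiguous range: beat frequency below Fs/2."""
        return self.Fs * C_LIGHT / (4.0 * self.slope)

    def beat_frequency(self, r: float) -> float:
        """Beat frequency 2*K*r/c (Hz) of a reflector at range ``r``."""
        return 2.0 * self.slope * r / C_LIGHT

    def range_axis(self, n_fft: int):
        """Map FFT bin index -> range (m) for an ``n_fft``-point range FFT."""
        import numpy as np

        df = self.Fs / n_fft
        # f_b = 2*K*R/c  =>  R = f_b * c / (2K)
        return np.arange(n_fft) * df * C_LIGHT / (2.0 * self.slope)

    def to_dict(self) -> dict:
        return {
            "fc": self.fc,
            "Tc": self.Tc,
            "slope": self.slope,
            "Fs": self.Fs,
            "Ts": self.Ts,
            "n_samples": self.n_samples,
            "n_frames": self.n_frames,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadarConfig":
        return cls(**d)
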