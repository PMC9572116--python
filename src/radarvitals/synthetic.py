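"""Synthetic FMCW I/Q data with known chest motion — the hardware stand-in.

Generates the two-dimensional beat-signal matrix (fast time x slow time) a
radar front end would produce for a single seated subject: a beat tone at the
target's range whose slow-time phase carries the chest displacement

    x(t) = breathing fundamental + breathing harmonics + heartbeat sinusoid,

plus static clutter reflectors, per-channel DC offsets, per-frame phase
noise, additive white Gaussian noise, and occasional impulse artifacts.
Every realization is fixed by an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import C_LIGHT, RadarConfig

__all__ = [
    "ChestMotionModel",
    "ImpairmentModel",
    "IQFrameMatrix",
    "chest_displacement",
    "simulate_cube",
    "inject_impulses",
    "typical_impairments",
]


@dataclass(frozen=True)
class ChestMotionModel:
    """Chest-wall displacement model of one subject.

    Breathing moves the chest wall by a few millimetres at 0.1-0.6 Hz; the
    heartbeat adds a ~0.1 mm ripple at 0.8-2.5 Hz.  Radar nonlinearity and
    the non-sinusoidal shape of real breathing are captured by relative
    harmonic amplitudes of the breathing fundamental (orders 2..4).
    """

    R0: float = 1.0  # standoff range (m)
    breath_amp: float = 1.0e-3  # m
    breath_freq: float = 0.3  # Hz
    heart_amp: float = 1.0e-4  # m
    heart_freq: float = 1.2  # Hz
    harmonic_coeffs: tuple = (0.15, 0.06, 0.02)  # relative amps of orders 2..4
    breath_phase: float = 0.0  # rad
    heart_phase: float = 0.0  # rad
    intermodulation: float = 0.0  # relative amp of breathing x heartbeat term

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.breath_amp < 0 or self.heart_amp < 0:
            raise ValueError("displacement amplitudes must be >= 0")
        if any(c < 0 for c in self.harmonic_coeffs):
            raise ValueError("harmonic coefficients must be >= 0")
        if self.heart_amp > self.breath_amp > 0:
            warnings.warn(
                "heart_amp exceeds breath_amp — atypical physiology",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "breath_amp": self.breath_amp,
            "breath_freq": self.breath_freq,
            "heart_amp": self.heart_amp,
            "heart_freq": self.heart_freq,
            "harmonic_coeffs": list(self.harmonic_coeffs),
            "breath_phase": self.breath_phase,
            "heart_phase": self.heart_phase,
            "intermodulation": self.intermodulation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChestMotionModel":
        d = dict(d)
        if "harmonic_coeffs" in d:
            d["harmonic_coeffs"] = tuple(d["harmonic_coeffs"])
        return cls(**d)


@dataclass(frozen=True)
class ImpairmentModel:
    """Hardware / environment impairments applied to the simulated cube.

    ``clutter`` lists static reflectors as ``(range_m, amplitude)`` pairs;
    they produce beat tones with no slow-time modulation.  ``impulse_rate``
    is the expected number of corrupted frames per frame as a fraction
    (events per frame), each adding a complex spike of amplitude
    ``impulse_amp`` to every fast-time sample of that frame.
    """

    dc_i: float = 0.0
    dc_q: float = 0.0
    phase_noise_std: float = 0.0  # rad, i.i.d. per frame and channel
    awgn_std: float = 0.0  # amplitude units, per sample and channel
    impulse_rate: float = 0.0  # corrupted-frame probability per frame
    impulse_amp: float = 0.0
    clutter: tuple = ()  # ((range_m, amplitude), ...)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("phase_noise_std", "awgn_std", "impulse_rate", "impulse_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "dc_i": self.dc_i,
            "dc_q": self.dc_q,
            "phase_noise_std": self.phase_noise_std,
            "awgn_std": self.awgn_std,
            "impulse_rate": self.impulse_rate,
            "impulse_amp": self.impulse_amp,
            "clutter": [list(c) for c in self.clutter],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImpairmentModel":
        d = dict(d)
        if "clutter" in d:
            d["clutter"] = tuple(tuple(c) for c in d["clutter"])
        return cls(**d)


@dataclass
class IQFrameMatrix:
    """Complex beat-signal cube: fast-time samples x slow-time frames."""

    data: np.ndarray  # complex, (n_samples, n_frames)
    config: RadarConfig
    truth: ChestMotionModel | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.shape != (self.config.n_samples, self.config.n_frames):
            raise ValueError(
                f"cube shape {self.data.shape} does not match config "
                f"({self.config.n_samples}, {self.config.n_frames})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite entries")


def chest_displacement(motion: ChestMotionModel, t: np.ndarray) -> np.ndarray:
    """Evaluate the chest displacement x(t) (m) on a time grid (s).

    Sine convention: each component is ``amp * sin(2*pi*f*t + phase)``, so
    x(0) = 0 for zero phase offsets.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("time grid is empty")
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("time grid must be 1-D and strictly increasing")

    m = motion
    breath = np.sin(2 * np.pi * m.breath_freq * t + m.breath_phase)
    x = m.breath_amp * breath
    for order, coeff in enumerate(m.harmonic_coeffs, start=2):
        x = x + m.breath_amp * coeff * np.sin(
            2 * np.pi * order * m.breath_freq * t + m.breath_phase
        )
    heart = np.sin(2 * np.pi * m.heart_freq * t + m.heart_phase)
    x = x + m.heart_amp * heart
    if m.intermodulation > 0:
        x = x + m.intermodulation * m.breath_amp * breath * heart
    return x


def simulate_cube(
    config: RadarConfig,
    motion: ChestMotionModel,
    imp: ImpairmentModel | None = None,
) -> IQFrameMatrix:
    """Simulate the I/Q beat-signal matrix for one observation.

    For frame ``n`` at fast time ``t`` the clean beat signal is::

        s(t, n) = Ar * exp(j * (2*pi*fb*t + 4*pi*x(n*Ts)/lambda + 4*pi*R0/lambda))

    with ``fb = 2*K*R0/c`` and unit amplitude ``Ar``.  Static clutter adds
    equivalent tones with time-constant phase; DC offsets, per-frame phase
    noise, white noise and frame impulses are then applied per ``imp``.
    """
    imp = imp if imp is not None else ImpairmentModel()
    if motion.R0 >= config.max_range:
        raise ValueError(
            f"target range {motion.R0} m is beyond the unambiguous maximum "
            f"{config.max_range:.3g} m for Fs={config.Fs:.3g}"
        )
    for r_c, _ in imp.clutter:
        if r_c >= config.max_range:
            raise ValueError(
                f"clutter range {r_c} m beyond unambiguous maximum "
                f"{config.max_range:.3g} m"
            )

    rng = np.random.default_rng(imp.seed)
    lam = config.lambda_max
    t_fast = np.arange(config.n_samples) / config.Fs  # (S,)
    t_slow = np.arange(config.n_frames) * config.Ts  # (F,)

    x = chest_displacement(motion, t_slow)  # (F,)
    fb = config.beat_frequency(motion.R0)
    slow_phase = 4 * np.pi * x / lam + 4 * np.pi * motion.R0 / lam  # (F,)
    cube = np.exp(
        1j * (2 * np.pi * fb * t_fast[:, None] + slow_phase[None, :])
    )

    for r_c, amp_c in imp.clutter:
        fb_c = config.beat_frequency(r_c)
        tone = amp_c * np.exp(
            1j * (2 * np.pi * fb_c * t_fast + 4 * np.pi * r_c / lam)
        )
        cube = cube + tone[:, None]

    if imp.phase_noise_std > 0:
        # Independent per-frame phase jitter on each channel, as in the
        # I/Q model where the two channels carry separate phase-noise terms.
        dphi_i = rng.normal(0.0, imp.phase_noise_std, config.n_frames)
        dphi_q = rng.normal(0.0, imp.phase_noise_std, config.n_frames)
        re = np.cos(np.angle(cube) + dphi_i[None, :]) * np.abs(cube)
        im = np.sin(np.angle(cube) + dphi_q[None, :]) * np.abs(cube)
        cube = re + 1j * im

    cube = cube + (imp.dc_i + 1j * imp.dc_q)

    if imp.awgn_std > 0:
        noise = rng.normal(0.0, imp.awgn_std, cube.shape) + 1j * rng.normal(
            0.0, imp.awgn_std, cube.shape
        )
        cube = cube + noise

    if imp.impulse_rate > 0 and imp.impulse_amp > 0:
        # Wideband interference bursts: a hit frame gets an independent
        # complex spike on every fast-time sample, so the burst spreads
        # over all range bins and shows up as a slow-time outlier (an
        # impulse in the phase-difference signal) at the target bin.
        hit = rng.random(config.n_frames) < imp.impulse_rate
        n_hit = int(hit.sum())
        if n_hit:
            burst = imp.impulse_amp * (
                rng.normal(0.0, 1.0, (config.n_samples, n_hit))
                + 1j * rng.normal(0.0, 1.0, (config.n_samples, n_hit))
            ) / np.sqrt(2.0)
            cube[:, hit] += burst

    return IQFrameMatrix(data=cube, config=config, truth=motion)


def typical_impairments(seed: int = 0) -> ImpairmentModel:
    """Moderate office-scenario impairments used as the standard test
    condition: small per-channel DC offsets (~10% of the beat amplitude),
    20 mrad per-frame phase jitter, -20 dB-per-sample white noise, two
    static clutter reflectors bracketing the subject, and wideband
    interference bursts hitting ~2% of frames at 10x the beat amplitude.
    """
    return ImpairmentModel(
        dc_i=0.1,
        dc_q=-0.08,
        phase_noise_std=0.02,
        awgn_std=0.1,
        impulse_rate=0.02,
        impulse_amp=10.0,
        clutter=((0.5, 0.8), (2.0, 0.5)),
        seed=seed,
    )


def inject_impulses(
    series: np.ndarray, imp: ImpairmentModel
) -> tuple[np.ndarray, np.ndarray]:
    """Add isolated spikes to a 1-D series; returns (corrupted, positions).

    Draws ``round(impulse_rate * len(series))`` distinct positions from the
    seeded generator and adds ``impulse_amp`` with random sign at each.
    """
    series = np.asarray(series, dtype=float)
    rng = np.random.default_rng(imp.seed)
    n = series.size
    n_spikes = int(round(imp.impulse_rate * n))
    if n_spikes == 0:
        return series.copy(), np.empty(0, dtype=int)
    pos = rng.choice(n, size=min(n_spikes, n), replace=False)
    signs = rng.choice([-1.0, 1.0], size=pos.size)
    out = series.copy()
    out[pos] += signs * imp.impulse_amp
    return out, np.sort(pos)
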