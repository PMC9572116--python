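"""Range processing: fast-time FFT, static-clutter removal, bin selection.

The fast-time FFT of each chirp turns the cube into a range/slow-time
matrix.  Stationary reflectors (walls, furniture) give rows that are
constant over slow time; subtracting each row's slow-time mean removes them
while preserving the moving target's modulation.  The target's range bin is
then the row with the largest slow-time variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .config import RadarConfig
from .synthetic import IQFrameMatrix

__all__ = [
    "RangeProfileMatrix",
    "RangeBinSelection",
    "range_fft",
    "remove_static_clutter",
    "select_range_bin",
]


@dataclass
class RangeProfileMatrix:
    """Complex range/slow-time matrix with its bin -> range mapping."""

    data: np.ndarray  # (n_bins, n_frames)
    bin_to_range: np.ndarray  # (n_bins,) metres, monotone increasing
    config: RadarConfig

    def __post_init__(self) -> None:
        if self.data.shape[0] != self.bin_to_range.shape[0]:
            raise ValueError("bin_to_range length must equal number of bins")
        if np.any(np.diff(self.bin_to_range) <= 0):
            raise ValueError("bin_to_range must be monotone increasing")


@dataclass
class RangeBinSelection:
    """Selected target bin and its slow-time series."""

    bin_index: int
    slow_time: np.ndarray  # complex, (n_frames,)
    selection_score: float


def range_fft(
    cube: IQFrameMatrix, n_fft: int | None = None, window: str = "hann"
) -> RangeProfileMatrix:
    """Column-wise FFT over fast time (the range FFT).

    Parameters
    ----------
    n_fft : int, optional
        FFT length; defaults to ``n_samples`` (no zero padding).
    window : str
        Fast-time window name (any scipy window), or ``"rect"`` /
        ``"boxcar"`` for none.  Hann by default for sidelobe control.
    """
    cfg = cube.config
    if n_fft is None:
        n_fft = cfg.n_samples
    if n_fft < cfg.n_samples:
        raise ValueError(
            f"n_fft={n_fft} must be >= n_samples={cfg.n_samples}"
        )
    if window in ("rect", "rectangular", "boxcar", None):
        w = np.ones(cfg.n_samples)
    else:
        w = get_window(window, cfg.n_samples, fftbins=True)
    spect = np.fft.fft(cube.data * w[:, None], n=n_fft, axis=0)
    return RangeProfileMatrix(
        data=spect, bin_to_range=cfg.range_axis(n_fft), config=cfg
    )


def remove_static_clutter(rp: RangeProfileMatrix) -> RangeProfileMatrix:
    """Subtract each range bin's slow-time mean (static-clutter removal)."""
    if rp.data.shape[1] < 2:
        raise ValueError(
            "static-clutter removal needs at least 2 frames "
            "(slow-time mean is degenerate for a single frame)"
        )
    cleaned = rp.data - rp.data.mean(axis=1, keepdims=True)
    return RangeProfileMatrix(
        data=cleaned, bin_to_range=rp.bin_to_range, config=rp.config
    )


def select_range_bin(rp: RangeProfileMatrix) -> RangeBinSelection:
    """Pick the range bin with maximal slow-time variance.

    Assumes static clutter has been removed; a breathing target then
    dominates the variance at its own bin.  Ties go to the lowest index.
    """
    if not np.any(rp.data):
        raise ValueError("all-zero range profile: no target to select")
    scores = np.var(np.abs(rp.data), axis=1)
    bin_index = int(np.argmax(scores))  # argmax takes the first maximum
    return RangeBinSelection(
        bin_index=bin_index,
        slow_time=rp.data[bin_index].copy(),
        selection_score=float(scores[bin_index]),
    )
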