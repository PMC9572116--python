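"""Phase demodulation of the slow-time signal at the target range bin.

The selected bin's complex series traces an arc of a circle whose angle is
proportional to chest displacement.  Residual DC offsets (mixer leakage,
antenna coupling) shift the circle's centre away from the origin and distort
an arctangent phase read-out, so the centre is first estimated by circle
fitting and subtracted.  The phase itself is integrated with the extended
differentiate-and-cross-multiply (DACM) recursion, which is immune to the
+-pi wrap discontinuities of the arctangent:

    psi(n) = sum_{i<=n} [I(i) dQ(i) - Q(i) dI(i)] / (I(i)^2 + Q(i)^2).

A first-order difference of the phase then equalises the spectrum in favour
of the (weak, higher-frequency) heartbeat component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CircleFit",
    "PhaseSeries",
    "fit_circle_nlls",
    "compensate_dc",
    "extract_phase_dacm",
    "phase_difference",
]


@dataclass(frozen=True)
class CircleFit:
    """Estimated I/Q constellation circle (centre = DC offset)."""

    center_i: float
    center_q: float
    radius: float
    residual: float  # RMS of (distance-to-centre - radius)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


@dataclass
class PhaseSeries:
    """Slow-time phase-derived series with its sampling rate."""

    values: np.ndarray
    fs_slow: float  # Hz
    kind: Literal["phase", "phase_diff", "displacement"] = "phase"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_slow <= 0:
            raise ValueError("fs_slow must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase series contains non-finite values")

    def to_displacement(self, lambda_max: float) -> "PhaseSeries":
        """Convert radians to metres: x = psi * lambda / (4*pi)."""
        if self.kind == "displacement":
            return self
        return PhaseSeries(
            values=self.values * lambda_max / (4 * np.pi),
            fs_slow=self.fs_slow,
            kind="displacement",
        )


def _kasa_fit(i: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) circle fit: linear least squares on
    x^2 + y^2 = 2*a*x + 2*b*y + c, centre (a, b), radius sqrt(c + a^2 + b^2)."""
    A = np.column_stack([2 * i, 2 * q, np.ones_like(i)])
    b = i**2 + q**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate constellation: points are collinear")
    a, b0, c = sol
    r2 = c + a**2 + b0**2
    if r2 <= 0:
        raise ValueError("degenerate constellation: non-positive radius")
    return float(a), float(b0), float(np.sqrt(r2))


def fit_circle_nlls(slow_time: np.ndarray) -> CircleFit:
    """Fit centre and radius of the I/Q constellation by nonlinear least
    squares (geometric distance), seeded with the algebraic Kasa fit.
    """
    z = np.asarray(slow_time, dtype=complex).ravel()
    if z.size < 3:
        raise ValueError("need at least 3 points to fit a circle")
    i, q = z.real, z.imag
    # Collinearity check via the rank of centred coordinates.
    pts = np.column_stack([i - i.mean(), q - q.mean()])
    s = np.linalg.svd(pts, compute_uv=False)
    if s[-1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate constellation: points are collinear")

    ci0, cq0, r0 = _kasa_fit(i, q)

    def resid(p):
        return np.hypot(i - p[0], q - p[1]) - p[2]

    sol = least_squares(
        resid,
        x0=[ci0, cq0, r0],
        method="lm",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=100 * 3,
    )
    ci, cq, r = sol.x
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return CircleFit(center_i=float(ci), center_q=float(cq), radius=float(abs(r)), residual=rms)


def compensate_dc(slow_time: np.ndarray, fit: CircleFit) -> np.ndarray:
    """Shift the constellation centre to the origin."""
    z = np.asarray(slow_time, dtype=complex)
    return z - (fit.center_i + 1j * fit.center_q)


def extract_phase_dacm(slow_time: np.ndarray, fs_slow: float = 20.0) -> PhaseSeries:
    """Extended-DACM phase demodulation of a complex series.

    The cumulative sum starts at 0; the result is continuous (no wraps).
    Raises if any sample has zero magnitude (the recursion divides by
    I^2 + Q^2).
    """
    z = np.asarray(slow_time, dtype=complex).ravel()
    mag2 = z.real**2 + z.imag**2
    bad = np.flatnonzero(mag2 == 0)
    if bad.size:
        raise ValueError(f"zero-magnitude sample at index {bad[0]}")
    i, q = z.real, z.imag
    di = np.diff(i)
    dq = np.diff(q)
    # Backward-difference integrand at samples 1..n-1.
    incr = (i[1:] * dq - q[1:] * di) / mag2[1:]
    psi = np.concatenate([[0.0], np.cumsum(incr)])
    return PhaseSeries(values=psi, fs_slow=fs_slow, kind="phase")


def phase_difference(ps: PhaseSeries) -> PhaseSeries:
    """First-order forward difference of the phase (length n-1).

    Differencing multiplies a sinusoid at frequency f by 2*sin(pi*f/fs),
    boosting the heartbeat band relative to breathing.
    """
    if ps.kind != "phase":
        raise ValueError(f"expected kind='phase', got {ps.kind!r}")
    if ps.values.size < 2:
        raise ValueError("need at least 2 samples to difference")
    return PhaseSeries(
        values=np.diff(ps.values), fs_slow=ps.fs_slow, kind="phase_diff"
    )
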