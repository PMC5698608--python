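"""Undecimated (a trous) quadratic spline wavelet transform.

The quadratic spline wavelet is the derivative of a smoothing kernel, so its
coefficients behave like a smoothed derivative of the signal at each dyadic
scale: a sharp pulse produces a positive modulus maximum on its upstroke and
a negative one on its downstroke, with a zero-crossing at the apex. Because
no decimation is performed every level keeps the input's length and sample
alignment, which is what makes zero-crossing localization straightforward.

Filters are the classic quadratic-spline pair used for singularity
detection: smoothing taps h = (0.125, 0.375, 0.375, 0.125) and derivative
taps g = (2, -2). At level i the taps are spread by 2^(i-1) samples
("holes"). Each output is advanced by its accumulated group delay so that a
symmetric pulse's zero-crossing lands on the apex to within a sample at
level 1; any residual half-sample bias at deeper levels is absorbed by the
detector's refinement step on the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Signal

__all__ = ["LOWPASS_TAPS", "HIGHPASS_TAPS", "QSplineDecomposition", "qspline_decompose"]

#: Smoothing (lowpass) taps; symmetric, sums to 1.
LOWPASS_TAPS = np.array([0.125, 0.375, 0.375, 0.125])
#: Derivative-like (highpass) taps; sums to 0, so constants are annihilated.
HIGHPASS_TAPS = np.array([2.0, -2.0])


@dataclass(frozen=True)
class QSplineDecomposition:
    """Detail series W_1..W_L plus the final smoothed approximation.

    Every series has the input's length (the transform is undecimated).
    """

    details: tuple
    approximation: np.ndarray
    fs: float
    levels: int

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.details) != self.levels:
            raise ValueError("expected one detail series per level")

    def detail(self, level: int) -> np.ndarray:
        """Detail coefficients W_level (1-based)."""
        if not 1 <= level <= self.levels:
            raise ValueError(f"level must be in 1..{self.levels}")
        return self.details[level - 1]


def _atrous_filter(x: np.ndarray, taps: np.ndarray, spacing: int) -> np.ndarray:
    """Causal a trous filtering: y[t] = sum_k taps[k] * x[t - k*spacing].

    The signal is extended by half-point symmetric reflection.
    """
    n = x.size
    pad = spacing * (taps.size - 1)
    xp = np.pad(x, (pad, 0), mode="symmetric")
    y = np.zeros(n)
    for k, v in enumerate(taps):
        lo = pad - k * spacing
        y += v * xp[lo : lo + n]
    return y


def _advance(y: np.ndarray, shift: int) -> np.ndarray:
    """Advance a series by ``shift`` samples (out[t] = y[t + shift])."""
    if shift <= 0:
        return y
    return np.pad(y, (0, shift), mode="symmetric")[shift:]


def qspline_decompose(signal: Signal, levels: int = 5) -> QSplineDecomposition:
    """Decompose a signal into ``levels`` undecimated detail series.

    At level i the previous approximation is convolved with the smoothing
    and derivative filters whose taps are spread by 2^(i-1) samples; the
    input itself serves as the level-0 approximation.

    Raises
    ------
    ValueError
        If the signal is shorter than the deepest level's filter support.
    """
    levels = int(levels)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = len(signal)
    support = 2 ** (levels - 1) * max(LOWPASS_TAPS.size, HIGHPASS_TAPS.size)
    if n <= support:
        raise ValueError(
            f"signal of {n} samples too short for {levels} levels "
            f"(needs more than {support} samples)"
        )
    approx = signal.samples
    details = []
    smooth_delay = 0.0  # accumulated group delay of the smoothing cascade
    for i in range(1, levels + 1):
        spacing = 2 ** (i - 1)
        w = _atrous_filter(approx, HIGHPASS_TAPS, spacing)
        w_delay = smooth_delay + 0.5 * spacing * (HIGHPASS_TAPS.size - 1)
        details.append(_advance(w, int(np.floor(w_delay + 0.5))))
        approx = _atrous_filter(approx, LOWPASS_TAPS, spacing)
        smooth_delay += 0.5 * spacing * (LOWPASS_TAPS.size - 1)
    approx = _advance(approx, int(np.floor(smooth_delay + 0.5)))
    return QSplineDecomposition(
        details=tuple(details), approximation=approx, fs=signal.fs, levels=levels
    )
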