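"""SpO2 from dual-wavelength PPG via the ratio-of-ratios.

Under the Lambert-Beer law the arterial oxygen saturation maps onto the
ratio of the two channels' normalized pulsatile absorbances,

    R = (dI_red / I_red) / (dI_ir / I_ir),        SpO2 ~= A * R + B,

where dI is the per-beat peak-to-trough excursion and I the peak value of
each channel; A and B come from a device calibration experiment and are
required inputs here. The exact logarithmic form
``A * lg(1 - dI'/I') / lg(1 - dI/I) + B`` is also available; the linear
form is the default first-order approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import PeakSet, Signal

__all__ = ["BeatFeatures", "SpO2Params", "SpO2Result", "pulse_features", "compute_spo2"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeatFeatures:
    """Per-beat peak and trough amplitudes of one channel."""

    peak_index: int
    peak_value: float
    trough_value: float

    @property
    def delta(self) -> float:
        """Peak-to-trough excursion dI_max (non-negative)."""
        return self.peak_value - self.trough_value


@dataclass(frozen=True)
class SpO2Params:
    """Calibration slope A and intercept B (device-specific)."""

    A: float
    B: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and math.isfinite(self.B)):
            raise ValueError("calibration coefficients must be finite")


@dataclass(frozen=True)
class SpO2Result:
    per_beat: tuple
    median: float


def pulse_features(signal: Signal, peaks: PeakSet) -> list[BeatFeatures]:
    """Peak value and preceding-trough value for every beat after the first.

    The trough is the signal minimum between the previous peak and the
    current one (current peak included, so the excursion is never negative).
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to extract beat features")
    x = signal.samples
    if peaks.indices[-1] >= x.size:
        raise ValueError("peak index beyond the end of the signal")
    out = []
    idx = peaks.indices
    for prev, cur in zip(idx[:-1], idx[1:]):
        trough = float(x[prev + 1 : cur + 1].min())
        out.append(BeatFeatures(peak_index=int(cur), peak_value=float(x[cur]), trough_value=trough))
    return out


def _match_beats(
    features_a: list[BeatFeatures], features_b: list[BeatFeatures], window: int
) -> list[tuple[BeatFeatures, BeatFeatures]]:
    """Pair beats across channels by nearest peak index, each used once."""
    used = [False] * len(features_b)
    pairs = []
    for fa in features_a:
        best, best_d = -1, window + 1
        for j, fb in enumerate(features_b):
            if used[j]:
                continue
            d = abs(fb.peak_index - fa.peak_index)
            if d <= window and d < best_d:
                best, best_d = j, d
        if best >= 0:
            used[best] = True
            pairs.append((fa, features_b[best]))
    return pairs


def compute_spo2(
    features_red: list[BeatFeatures],
    features_ir: list[BeatFeatures],
    params: SpO2Params,
    form: str = "linear",
    match_window: int = 30,
) -> SpO2Result:
    """Per-beat SpO2 and its median from matched red/IR beat features.

    The red channel enters the numerator of the ratio-of-ratios. Beats with
    zero pulsatility in the IR (denominator) channel, zero peak value in
    either channel, or — in the logarithmic form — a normalized excursion at
    or above 1, are skipped with a warning.

    Parameters
    ----------
    form
        ``"linear"`` (default) for ``A*R + B``; ``"log"`` for the exact
        logarithmic ratio.
    match_window
        Cross-channel beat matching tolerance in samples.
    """
    if form not in ("linear", "log"):
        raise ValueError("form must be 'linear' or 'log'")
    values = []
    for fr, fi in _match_beats(features_red, features_ir, match_window):
        if fr.peak_value == 0 or fi.peak_value == 0:
            logger.warning("beat at %d skipped: zero peak value", fr.peak_index)
            continue
        s_red = fr.delta / fr.peak_value
        s_ir = fi.delta / fi.peak_value
        if s_ir == 0:
            logger.warning("beat at %d skipped: zero pulsatility in the IR channel", fr.peak_index)
            continue
        if form == "log":
            if s_red >= 1 or s_ir >= 1:
                logger.warning(
                    "beat at %d skipped: normalized excursion >= 1, log form undefined",
                    fr.peak_index,
                )
                continue
            denom = math.log10(1.0 - s_ir)
            if denom == 0:
                continue
            ratio = math.log10(1.0 - s_red) / denom
        else:
            ratio = s_red / s_ir
        values.append(params.A * ratio + params.B)
    if not values:
        raise ValueError("no usable beats: all were skipped")
    return SpO2Result(per_beat=tuple(values), median=float(np.median(values)))
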