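"""Detector scoring against reference annotations.

Detections are matched one-to-one to reference beats within a tolerance
window; the headline figure is the error percentage

    error = (FP + FN) / RB * 100

where RB is the number of real (reference) beats, FP the spurious
detections and FN the missed beats.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .core import PeakSet

__all__ = ["EvaluationResult", "match_peaks", "detection_error", "evaluate_detection"]


@dataclass(frozen=True)
class EvaluationResult:
    """Beat counts and the resulting detection error percentage."""

    RB: int
    TP: int
    FP: int
    FN: int
    error_percent: float

    def __post_init__(self) -> None:
        if self.RB < 1:
            raise ValueError("RB must be >= 1")
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if abs(self.error_percent - 100.0 * (self.FP + self.FN) / self.RB) > 0.01:
            raise ValueError("error percentage inconsistent with the counts")

    def to_dict(self) -> dict:
        return {
            "RB": self.RB,
            "TP": self.TP,
            "FP": self.FP,
            "FN": self.FN,
            "error_percent": self.error_percent,
        }


def match_peaks(detected: PeakSet, reference: PeakSet, tolerance_ms: float = 150.0) -> tuple[int, int, int]:
    """One-to-one matching of detections to reference beats.

    Matches maximize the number of paired beats within ``+/-tolerance_ms``
    (ties broken by smaller total offset); the optimal matching of two
    sorted sequences on a line is non-crossing, so a dynamic program over
    the two sequences finds it exactly. Unmatched detections count as FP,
    unmatched references as FN.

    Returns
    -------
    (TP, FP, FN)
    """
    if detected.fs != reference.fs:
        raise ValueError("detected and reference peak sets use different sampling rates")
    tol = tolerance_ms / 1000.0 * detected.fs
    d = detected.indices
    r = reference.indices
    nd, nr = d.size, r.size
    # dp[i][j] = (matches, -total_offset) for d[:i] vs r[:j]
    NEG = (-1, 0.0)
    dp = [[NEG] * (nr + 1) for _ in range(nd + 1)]
    for i in range(nd + 1):
        dp[i][0] = (0, 0.0)
    for j in range(nr + 1):
        dp[0][j] = (0, 0.0)
    for i in range(1, nd + 1):
        for j in range(1, nr + 1):
            best = max(dp[i - 1][j], dp[i][j - 1])
            gap = abs(float(d[i - 1]) - float(r[j - 1]))
            if gap <= tol:
                m, s = dp[i - 1][j - 1]
                cand = (m + 1, s - gap)
                if cand > best:
                    best = cand
            dp[i][j] = best
    tp = dp[nd][nr][0]
    return tp, nd - tp, nr - tp


def detection_error(RB: int, FP: int, FN: int) -> float:
    """Error percentage ``100 * (FP + FN) / RB``, rounded half-up to 2 dp."""
    if RB < 1:
        raise ValueError("RB must be >= 1")
    if FP < 0 or FN < 0:
        raise ValueError("FP and FN must be non-negative")
    value = Decimal(100) * (Decimal(FP) + Decimal(FN)) / Decimal(RB)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def evaluate_detection(
    detected: PeakSet, reference: PeakSet, tolerance_ms: float = 150.0
) -> EvaluationResult:
    """Match and score a detection run against reference annotations."""
    if len(reference) < 1:
        raise ValueError("reference annotations must contain at least one beat")
    tp, fp, fn = match_peaks(detected, reference, tolerance_ms)
    rb = len(reference)
    return EvaluationResult(RB=rb, TP=tp, FP=fp, FN=fn, error_percent=detection_error(rb, fp, fn))
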