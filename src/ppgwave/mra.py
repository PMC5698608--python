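"""Baseline-drift suppression by wavelet multiresolution analysis.

Respiration and body movement put most of their energy below 1 Hz, while the
pulse wave itself lives in roughly 1-10 Hz. Decomposing a PPG window with a
symlet (sym8) down to the deepest level its length supports pushes the
sub-1-Hz content into the final approximation; reconstructing that
approximation alone estimates the baseline wander plus the low-frequency part
of motion artifacts, and subtracting it from the raw window corrects the
signal's amplitude without touching the pulse band.

The deepest usable level for a window of N samples and a wavelet filter of
lw taps is ``fix(log2(N / (lw - 1)))``; for the canonical 1024-sample,
100 Hz window with sym8 (16 taps) this gives 6 levels, whose approximation
band edge (~0.78 Hz) sits just under the 1 Hz drift/pulse boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import Signal

__all__ = [
    "SYM8_FILTER_LENGTH",
    "MRADecomposition",
    "max_decomposition_level",
    "decompose_mra",
    "recompose",
    "estimate_baseline",
    "correct_signal",
    "remove_baseline",
]

#: Filter length (taps) of the order-8 symlet used by default.
SYM8_FILTER_LENGTH = 16

#: Default processing block length in samples.
DEFAULT_BLOCK_SIZE = 1024

_DWT_MODE = "symmetric"  # half-point symmetric extension at the boundaries


@dataclass(frozen=True)
class MRADecomposition:
    """Dyadic wavelet decomposition: L detail layers plus one approximation.

    ``details[i]`` holds the level-(i+1) detail coefficients; ``approximation``
    the level-``level`` approximation coefficients. Perfect reconstruction of
    the original window holds to floating-point accuracy.
    """

    details: tuple
    approximation: np.ndarray
    level: int
    wavelet_id: str
    filter_length: int
    n_samples: int
    fs: float

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if len(self.details) != self.level:
            raise ValueError("expected one detail series per level")


def max_decomposition_level(n_samples: int, filter_length: int) -> int:
    """Deepest usable decomposition level: ``fix(log2(N / (lw - 1)))``.

    Parameters
    ----------
    n_samples
        Window length N; must be at least twice the filter length.
    filter_length
        Wavelet filter length lw in taps, at least 2.

    Raises
    ------
    ValueError
        If the window is too short to support even one level.
    """
    n_samples = int(n_samples)
    filter_length = int(filter_length)
    if filter_length < 2:
        raise ValueError("filter_length must be >= 2")
    if n_samples < 2 * filter_length:
        raise ValueError(
            f"no valid decomposition level: window of {n_samples} samples is "
            f"shorter than twice the {filter_length}-tap filter"
        )
    level = int(np.log2(n_samples / (filter_length - 1)))
    if level < 1:  # unreachable given the length guard, kept as a safety net
        raise ValueError("no valid decomposition level for these inputs")
    return level


def _wavelet(wavelet_id: str) -> pywt.Wavelet:
    return pywt.Wavelet(wavelet_id)


def decompose_mra(signal: Signal, wavelet_id: str = "sym8", level: int | None = None) -> MRADecomposition:
    """Decompose a signal into ``level`` details plus one approximation.

    ``level=None`` selects the deepest level the window length supports.
    """
    w = _wavelet(wavelet_id)
    lw = w.dec_len
    lmax = max_decomposition_level(len(signal), lw)
    if level is None:
        level = lmax
    level = int(level)
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    if level > lmax:
        raise ValueError(
            f"level {level} too deep for a {len(signal)}-sample window "
            f"(maximum {lmax} with the {lw}-tap {wavelet_id} filter)"
        )
    coeffs = pywt.wavedec(signal.samples, w, mode=_DWT_MODE, level=level)
    # pywt order: [cA_L, cD_L, ..., cD_1]; store details as level 1..L.
    details = tuple(reversed(coeffs[1:]))
    return MRADecomposition(
        details=details,
        approximation=coeffs[0],
        level=level,
        wavelet_id=wavelet_id,
        filter_length=lw,
        n_samples=len(signal),
        fs=signal.fs,
    )


def _pywt_coeffs(decomp: MRADecomposition, zero_details: bool = False) -> list:
    details = [np.zeros_like(d) if zero_details else d for d in reversed(decomp.details)]
    return [decomp.approximation] + details


def recompose(decomp: MRADecomposition) -> np.ndarray:
    """Invert the decomposition back to the original window."""
    out = pywt.waverec(_pywt_coeffs(decomp), _wavelet(decomp.wavelet_id), mode=_DWT_MODE)
    return out[: decomp.n_samples]


def estimate_baseline(decomp: MRADecomposition, out_length: int | None = None) -> Signal:
    """Reconstruct the top-level approximation alone (details zeroed).

    This is the sub-band estimate of baseline drift plus the low-frequency
    component of motion artifacts.
    """
    if out_length is None:
        out_length = decomp.n_samples
    out_length = int(out_length)
    base = pywt.waverec(
        _pywt_coeffs(decomp, zero_details=True), _wavelet(decomp.wavelet_id), mode=_DWT_MODE
    )
    if base.size < out_length:
        raise ValueError("requested output length exceeds the reconstructed window")
    return Signal(base[:out_length], decomp.fs, label="baseline")


def correct_signal(signal: Signal, baseline: Signal) -> Signal:
    """Subtract the estimated baseline pointwise from the raw signal."""
    if len(signal) != len(baseline):
        raise ValueError("signal and baseline lengths differ")
    if signal.fs != baseline.fs:
        raise ValueError("signal and baseline sampling rates differ")
    return signal.with_samples(signal.samples - baseline.samples)


def remove_baseline(
    signal: Signal,
    wavelet_id: str = "sym8",
    level: int | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> tuple[Signal, Signal]:
    """Estimate and subtract the baseline, block by block.

    Windows longer than ``block_size`` are processed in non-overlapping core
    blocks. Each core block is decomposed together with a half-block context
    margin on either side (where available) so the boundary extension does
    not leak pulse energy into the baseline at block joints; only the core's
    baseline samples are kept. The decomposition level follows the
    deepest-level rule applied to the core block length, so the baseline
    band does not depend on how much margin a block happens to have. A
    trailing remainder shorter than a full block is merged into the
    preceding block (a short block's own deepest level would widen the
    baseline band into the pulse band); a whole record too short to support
    one level falls back to mean subtraction.

    Returns
    -------
    (corrected, baseline)
        Both the same length and sampling rate as the input.
    """
    x = signal.samples
    n = x.size
    lw = _wavelet(wavelet_id).dec_len
    margin = block_size // 2
    base = np.empty(n)
    starts = list(range(0, n, block_size))
    if len(starts) > 1 and n - starts[-1] < block_size:
        starts.pop()
    for k, start in enumerate(starts):
        stop = starts[k + 1] if k + 1 < len(starts) else n
        core = x[start:stop]
        if core.size < 2 * lw:
            base[start:stop] = core.mean()
            continue
        # Auto level follows the nominal block length: a merged (longer)
        # trailing block must keep the same baseline band as a full block,
        # not a deeper level whose narrower band under-removes the drift.
        blk_level = (
            level
            if level is not None
            else max_decomposition_level(min(core.size, block_size), lw)
        )
        lo = max(0, start - margin)
        hi = min(n, stop + margin)
        ext = Signal(x[lo:hi], signal.fs)
        blk_level = min(int(blk_level), max_decomposition_level(len(ext), lw))
        decomp = decompose_mra(ext, wavelet_id, blk_level)
        ext_base = estimate_baseline(decomp, len(ext)).samples
        base[start:stop] = ext_base[start - lo : start - lo + core.size]
    baseline = signal.with_samples(base, label="baseline")
    return correct_signal(signal, baseline), baseline
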