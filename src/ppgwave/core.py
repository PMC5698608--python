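"""Core containers shared by every processing stage.

A :class:`Signal` is a uniformly sampled amplitude series with its sampling
rate; a :class:`PeakSet` is a strictly increasing sequence of 0-based sample
indices marking systolic apexes (detected or reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Signal", "PeakSet"]


@dataclass(frozen=True)
class Signal:
    """Uniformly sampled amplitude series.

    Parameters
    ----------
    samples
        Amplitude values (arbitrary units, typically normalized to [0, 1]).
        Must be finite and contain at least two samples.
    fs
        Sampling rate in Hz, strictly positive.
    label
        Free-text channel name (e.g. ``"red"``, ``"ir"``).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1:
            raise ValueError("signal samples must be one-dimensional")
        if x.size < 2:
            raise ValueError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("signal samples must all be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (t = k / fs)."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "Signal":
        """Return a copy carrying new samples but the same sampling rate."""
        return Signal(samples, self.fs, self.label if label is None else label)


@dataclass(frozen=True)
class PeakSet:
    """Strictly increasing 0-based peak sample indices at a sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64).ravel()
        if idx.size and (np.any(idx < 0) or np.any(np.diff(idx) <= 0)):
            raise ValueError("peak indices must be non-negative and strictly increasing")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.indices / self.fs

    def intervals(self) -> np.ndarray:
        """Peak-to-peak intervals in seconds (pulse intervals)."""
        return np.diff(self.indices) / self.fs
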