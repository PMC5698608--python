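"""Plain-text I/O: CSV signals and one-index-per-line peak annotations.

Signal files are CSV with either a ``time_s,amplitude`` header (sampling
rate inferred from the timestamps and checked for uniformity) or a single
``amplitude`` column (sampling rate must then be supplied). Peak files hold
one 0-based sample index per line. Lines starting with ``#`` are metadata
comments and are ignored on read; writers can embed provenance (seed,
config hash) in them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import PeakSet, Signal

__all__ = ["read_signal", "write_signal", "read_peaks", "write_peaks"]

#: Allowed relative timestamp jitter before a file is rejected as non-uniform.
MAX_TIME_JITTER = 0.01


class SignalFormatError(ValueError):
    """A signal or peak file violated the documented plain-text format."""


def _metadata_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in metadata.items())


def read_signal(path: str | Path, fs: float | None = None, label: str | None = None) -> Signal:
    """Read a CSV signal file; ``fs`` overrides/supplies the sampling rate."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise SignalFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(df.columns)
    if cols == ["time_s", "amplitude"]:
        time = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
        amp = pd.to_numeric(df["amplitude"], errors="coerce").to_numpy(dtype=float)
        _check_numeric(path, time, "time_s")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise SignalFormatError(f"{path}: timestamps must be strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > MAX_TIME_JITTER * step:
            raise SignalFormatError(
                f"{path}: non-uniform timestamps (jitter exceeds {MAX_TIME_JITTER:.0%} of the step)"
            )
        file_fs = 1.0 / step
        if fs is None:
            fs = file_fs
    elif cols == ["amplitude"]:
        amp = pd.to_numeric(df["amplitude"], errors="coerce").to_numpy(dtype=float)
        if fs is None:
            raise SignalFormatError(
                f"{path}: single-column file has no timestamps; a sampling rate is required"
            )
    else:
        raise SignalFormatError(
            f"{path}: expected header 'time_s,amplitude' or 'amplitude', got {cols}"
        )
    _check_numeric(path, amp, "amplitude")
    return Signal(amp, fs, label if label is not None else path.stem)


def _check_numeric(path: Path, values: np.ndarray, column: str) -> None:
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        # +2: one for the header row, one for 1-based line numbering.
        raise SignalFormatError(
            f"{path}: non-numeric or missing {column} value at line {int(bad[0]) + 2}"
        )


def write_signal(signal: Signal, path: str | Path, metadata: dict | None = None) -> None:
    """Write ``time_s,amplitude`` CSV at full double precision."""
    path = Path(path)
    t = signal.times
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        fh.write("time_s,amplitude\n")
        for ti, xi in zip(t, signal.samples):
            fh.write(f"{float(ti)!r},{float(xi)!r}\n")


def read_peaks(path: str | Path, fs: float) -> PeakSet:
    """Read a peak-annotation file: one 0-based index per line."""
    path = Path(path)
    indices = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                idx = int(line)
            except ValueError as exc:
                raise SignalFormatError(f"{path}: non-integer index at line {lineno}") from exc
            if idx < 0:
                raise SignalFormatError(f"{path}: negative index at line {lineno}")
            if indices and idx <= indices[-1]:
                raise SignalFormatError(f"{path}: indices not strictly increasing at line {lineno}")
            indices.append(idx)
    return PeakSet(np.array(indices, dtype=np.int64), fs)


def write_peaks(peaks: PeakSet, path: str | Path, metadata: dict | None = None) -> None:
    """Write one 0-based peak index per line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_metadata_lines(metadata))
        for idx in peaks.indices:
            fh.write(f"{int(idx)}\n")
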