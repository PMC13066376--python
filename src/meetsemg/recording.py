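"""Multichannel sEMG recordings and their delimited-text serialization.

A recording is stored on disk as a comma-separated file with a mandatory
header ``time_s,ch1,...,chK,label`` and one sample per row.  Signal values
round-trip to better than 1e-9 relative precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = ["RawRecording", "read_recording", "write_recording", "GESTURE_NAMES"]

#: Canonical gesture-code -> name mapping for the six-gesture protocol.
#: Code 0 is reserved for unlabelled rest.
GESTURE_NAMES = {1: "TE", 2: "ME", 3: "FME", 4: "FMTE", 5: "FMRE", 6: "HC"}


@dataclass
class RawRecording:
    """A contiguous multichannel recording with per-sample gesture labels.

    Parameters
    ----------
    subject_id
        Free-form subject identifier (e.g. ``"S01"``).
    sample_rate
        Sampling frequency in samples/second; positive integer.
    signal
        Array of shape ``(n_channels, n_samples)`` in millivolts.
    labels
        Integer class code per sample; ``0`` marks unlabelled rest.
    """

    subject_id: str
    sample_rate: int
    signal: np.ndarray
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.signal.ndim != 2:
            raise InputError("signal must be a 2-D (channels x samples) array")
        if self.sample_rate <= 0:
            raise InputError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.signal.shape[1]:
            raise InputError(
                f"labels length {self.labels.shape} does not match "
                f"signal length {self.signal.shape[1]}"
            )
        if self.labels.size and self.labels.min() < 0:
            raise InputError("label codes must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def with_signal(self, signal: np.ndarray) -> "RawRecording":
        """Copy of this recording with the signal replaced, metadata kept."""
        return RawRecording(self.subject_id, self.sample_rate, signal, self.labels.copy())


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as CSV (``time_s, ch1..chK, label``)."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sample_rate
    cols: dict[str, np.ndarray] = {"time_s": t}
    for k in range(rec.n_channels):
        cols[f"ch{k + 1}"] = rec.signal[k]
    cols["label"] = rec.labels
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.12g")


def read_recording(
    path: str | Path, subject_id: str | None = None, sample_rate: int | None = None
) -> RawRecording:
    """Read a recording CSV written by :func:`write_recording`.

    The sample rate is inferred from the ``time_s`` column spacing unless
    given explicitly.  Malformed files (ragged rows, missing label column,
    non-numeric cells) raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:  # ragged row with too many fields
        raise FormatError(f"{path}: malformed CSV ({exc})") from None
    if "label" not in df.columns or "time_s" not in df.columns:
        raise FormatError(f"{path}: header must contain 'time_s' and 'label' columns")
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    if not chan_cols:
        raise FormatError(f"{path}: no channel columns (ch1..chK) found")
    chan_cols.sort(key=lambda c: int(c[2:]))

    numeric = {}
    for col in ["time_s", *chan_cols, "label"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        bad |= df[col].isna()  # short rows are filled with NaN by the parser
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: non-numeric or missing value in column '{col}' at line {line}"
            )
        numeric[col] = converted.to_numpy()

    if sample_rate is None:
        t = numeric["time_s"]
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer sample rate from fewer than 2 rows")
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise FormatError(f"{path}: time_s column is not increasing")
        sample_rate = int(round(1.0 / dt))

    signal = np.vstack([numeric[c] for c in chan_cols])
    labels = numeric["label"].astype(np.int64)
    if not np.allclose(numeric["label"], labels):
        raise FormatError(f"{path}: label column must hold integer class codes")
    return RawRecording(
        subject_id=subject_id or path.stem,
        sample_rate=sample_rate,
        signal=signal,
        labels=labels,
    )
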