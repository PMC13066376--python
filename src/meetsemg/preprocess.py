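"""Band-limiting, powerline removal, and overlapping-window segmentation.

The EMG band filter is a 4th-order Butterworth bandpass (10-500 Hz by
default) and the powerline filter a second-order IIR notch at 50 Hz; both
are applied forward-backward (zero phase) so that window labels stay
aligned with the signal.  ``order`` counts the overall filter order: the
default quartic bandpass is realised as ``scipy.signal.butter(order // 2,
..., btype="bandpass")``.

Windows follow a 0-based half-open convention: window ``i`` covers samples
``[i*S, i*S + W)`` where ``W = round(window_ms * fs / 1000)`` and
``S = round(W * (1 - overlap_fraction))``.  At the 256 ms / 25% defaults and
2000 Hz this gives W = 512, S = 384, so consecutive windows share 128
samples, and a 480,000-sample channel yields 1249 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InputError
from .recording import RawRecording

__all__ = [
    "FilterSpec",
    "WindowSet",
    "bandpass_filter",
    "notch_filter",
    "segment_windows",
    "bandpass_sos",
    "notch_ba",
]


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one filtering stage.

    kind            "bandpass" or "notch".
    low_hz/high_hz  bandpass edges (default 10-500 Hz EMG band).
    notch_hz        notch center (default 50 Hz powerline).
    order           overall bandpass order; must be even and >= 2.
    quality_factor  notch sharpness Q (center / -3 dB width).
    gain            passband amplification H.
    """

    kind: str = "bandpass"
    low_hz: float = 10.0
    high_hz: float = 500.0
    notch_hz: float = 50.0
    order: int = 4
    quality_factor: float = 30.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "notch"):
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        if self.order < 2 or self.order % 2:
            raise ConfigurationError("order must be even and >= 2")
        if self.kind == "bandpass" and not 0 < self.low_hz < self.high_hz:
            raise ConfigurationError(
                f"bandpass edges must satisfy 0 < low < high, got {self.low_hz}, {self.high_hz}"
            )
        if self.quality_factor <= 0:
            raise ConfigurationError("quality_factor must be positive")

    def validate_rate(self, sample_rate: int) -> None:
        nyq = sample_rate / 2
        if self.kind == "bandpass" and self.high_hz >= nyq:
            raise ConfigurationError(
                f"high_hz {self.high_hz} must lie below Nyquist {nyq} Hz"
            )
        if self.kind == "notch" and self.notch_hz >= nyq:
            raise ConfigurationError(
                f"notch_hz {self.notch_hz} must lie below Nyquist {nyq} Hz"
            )


def bandpass_sos(spec: FilterSpec, sample_rate: int) -> np.ndarray:
    """Second-order sections of the designed Butterworth bandpass."""
    spec.validate_rate(sample_rate)
    return sps.butter(
        spec.order // 2,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=sample_rate,
        output="sos",
    )


def notch_ba(spec: FilterSpec, sample_rate: int) -> tuple[np.ndarray, np.ndarray]:
    """(b, a) coefficients of the designed IIR notch."""
    spec.validate_rate(sample_rate)
    return sps.iirnotch(spec.notch_hz, spec.quality_factor, fs=sample_rate)


def _check_finite(rec: RawRecording) -> None:
    if not np.isfinite(rec.signal).all():
        raise InputError("signal contains NaN or Inf; refusing to filter")


def bandpass_filter(rec: RawRecording, spec: FilterSpec | None = None) -> RawRecording:
    """Zero-phase Butterworth bandpass of every channel.

    Output length, labels and channel count are unchanged.  The passband
    is scaled by ``spec.gain``.
    """
    spec = spec or FilterSpec(kind="bandpass")
    if spec.kind != "bandpass":
        raise ConfigurationError("bandpass_filter requires a bandpass FilterSpec")
    _check_finite(rec)
    sos = bandpass_sos(spec, rec.sample_rate)
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=-1) * spec.gain
    return rec.with_signal(filtered)


def notch_filter(rec: RawRecording, spec: FilterSpec | None = None) -> RawRecording:
    """Zero-phase IIR notch (50 Hz powerline by default) on every channel."""
    spec = spec or FilterSpec(kind="notch")
    if spec.kind != "notch":
        raise ConfigurationError("notch_filter requires a notch FilterSpec")
    _check_finite(rec)
    b, a = notch_ba(spec, rec.sample_rate)
    filtered = sps.filtfilt(b, a, rec.signal, axis=-1)
    return rec.with_signal(filtered)


@dataclass
class WindowSet:
    """Fixed-length overlapping segments with one label per window.

    windows  array of shape (n_windows, n_channels, window_len).
    starts   0-based sample index of each window start.
    """

    windows: np.ndarray = field(repr=False)
    window_len: int
    step: int
    labels: np.ndarray
    starts: np.ndarray
    sample_rate: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.windows.ndim != 3 or self.windows.shape[2] != self.window_len:
            raise InputError("windows must have shape (n, K, W)")
        if len(self.labels) != len(self.windows) or len(self.starts) != len(self.windows):
            raise InputError("labels/starts length must equal window count")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]


def segment_windows(
    rec: RawRecording, window_ms: float = 256.0, overlap_fraction: float = 0.25
) -> WindowSet:
    """Cut a recording into overlapping fixed-length windows.

    Trailing samples that do not fill a complete window are dropped.  Each
    window's label is the majority of its per-sample labels, ties broken
    toward the lower class code.
    """
    if not 0 <= overlap_fraction < 1:
        raise ConfigurationError(
            f"overlap_fraction must lie in [0, 1), got {overlap_fraction}"
        )
    w = int(round(window_ms * rec.sample_rate / 1000.0))
    s = int(round(w * (1.0 - overlap_fraction)))
    if w < 2 or s < 1:
        raise ConfigurationError(f"degenerate window geometry W={w}, S={s}")
    length = rec.n_samples
    if length < w:
        raise InputError(
            f"signal length {length} is below the minimum of one window ({w} samples)"
        )
    n = (length - w) // s + 1
    starts = np.arange(n) * s
    # strided view over the sample axis, then select stepped starts
    view = np.lib.stride_tricks.sliding_window_view(rec.signal, w, axis=-1)
    windows = np.ascontiguousarray(view[:, starts, :].transpose(1, 0, 2))

    label_view = np.lib.stride_tricks.sliding_window_view(rec.labels, w)[starts]
    n_codes = int(rec.labels.max()) + 1
    counts = np.stack([(label_view == code).sum(axis=1) for code in range(n_codes)], axis=1)
    labels = counts.argmax(axis=1)  # argmax takes the lowest code on ties

    return WindowSet(
        windows=windows,
        window_len=w,
        step=s,
        labels=labels.astype(np.int64),
        starts=starts,
        sample_rate=rec.sample_rate,
        subject_id=rec.subject_id,
    )
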