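"""The 17-feature window representation used for gesture classification.

Eleven time-domain features and six frequency-domain features are computed
per window and channel.  The normative formulas, for a window
``x = x_0..x_{W-1}`` with differences ``d_i = x_{i+1} - x_i``:

time domain
    MAV   mean |x|
    VAR   sum (x - mean x)^2 / (W - 1)
    DASDV sqrt( sum d^2 / (W - 1) )
    WL    sum |d|                       (waveform length)
    IEMG  sum |x|                       (integrated EMG)
    LOG   exp( mean log(|x| + eps) )    (log detector)
    RMS   sqrt( mean x^2 )
    AAC   WL / (W - 1)                  (average amplitude change)
    ZC    #{ i : x_i * x_{i+1} < 0 and |d_i| >= zc_threshold }
    WAMP  #{ i : |d_i| >= wamp_threshold }        (Willison amplitude)
    MYOP  mean 1[ |x_i| >= myop_threshold ]       (myopulse rate)

frequency domain, from the one-sided power spectrum P_j at frequencies f_j
(periodogram with a rectangular window, "spectrum" scaling, so that
sum P_j = mean x^2 — Parseval):
    TTP   sum P_j                       (total power)
    MNP   mean P_j                      (mean power)
    PKF   f at max P_j                  (peak frequency)
    MNF   sum f_j P_j / sum P_j         (mean frequency)
    MDF   smallest f_m with cumulative power >= TTP / 2 (median frequency)
    FR    low-band power / high-band power, split at fr_band_split_hz

FR of a window with no high-band power (e.g. an all-zero window) is
reported as the sentinel 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, InputError
from .preprocess import WindowSet

__all__ = [
    "FeatureParams",
    "FeatureMatrix",
    "TIME_FEATURES",
    "FREQ_FEATURES",
    "FEATURE_NAMES",
    "time_domain_features",
    "frequency_domain_features",
    "featurize",
]

TIME_FEATURES = (
    "MAV", "VAR", "DASDV", "WL", "IEMG", "LOG", "RMS", "AAC", "ZC", "WAMP", "MYOP",
)
FREQ_FEATURES = ("TTP", "FR", "MDF", "PKF", "MNF", "MNP")
#: canonical per-channel feature ordering
FEATURE_NAMES = TIME_FEATURES + FREQ_FEATURES


@dataclass(frozen=True)
class FeatureParams:
    """Thresholds and spectral options of the feature extractor.

    Thresholds are absolute amplitudes on the (millivolt-scale) signal;
    the zero-crossing threshold applies to the step between the two
    samples bracketing a crossing.
    """

    zc_threshold: float = 0.0
    wamp_threshold: float = 0.01
    myop_threshold: float = 0.016
    log_epsilon: float = 1e-12
    psd_method: str = "periodogram"
    fr_band_split_hz: float = 250.0

    def __post_init__(self) -> None:
        if min(self.zc_threshold, self.wamp_threshold, self.myop_threshold) < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if self.psd_method not in ("periodogram", "welch"):
            raise ConfigurationError(f"unknown psd_method {self.psd_method!r}")
        if self.fr_band_split_hz <= 0:
            raise ConfigurationError("fr_band_split_hz must be positive")


def _check_window(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < min_len:
        raise InputError(f"window must be 1-D with at least {min_len} samples")
    if not np.isfinite(x).all():
        raise InputError("window contains non-finite values")
    return x


def time_domain_features(
    x: np.ndarray, params: FeatureParams | None = None
) -> dict[str, float]:
    """The 11 time-domain features of a single-channel window."""
    params = params or FeatureParams()
    x = _check_window(x, 2)
    w = x.size
    d = np.diff(x)
    abs_x = np.abs(x)
    wl = float(np.sum(np.abs(d)))
    out = {
        "MAV": float(np.mean(abs_x)),
        "VAR": float(np.sum((x - x.mean()) ** 2) / (w - 1)),
        "DASDV": float(np.sqrt(np.sum(d**2) / (w - 1))),
        "WL": wl,
        "IEMG": float(np.sum(abs_x)),
        "LOG": float(np.exp(np.mean(np.log(abs_x + params.log_epsilon)))),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "AAC": wl / (w - 1),
        "ZC": float(
            np.sum((x[:-1] * x[1:] < 0) & (np.abs(d) >= params.zc_threshold))
        ),
        "WAMP": float(np.sum(np.abs(d) >= params.wamp_threshold)),
        "MYOP": float(np.mean(abs_x >= params.myop_threshold)),
    }
    return out


def _power_spectrum(
    x: np.ndarray, sample_rate: float, params: FeatureParams
) -> tuple[np.ndarray, np.ndarray]:
    if params.psd_method == "periodogram":
        return sps.periodogram(
            x, fs=sample_rate, window="boxcar", scaling="spectrum", detrend=False
        )
    return sps.welch(
        x,
        fs=sample_rate,
        window="boxcar",
        nperseg=min(256, x.size),
        scaling="spectrum",
        detrend=False,
    )


def frequency_domain_features(
    x: np.ndarray, sample_rate: float, params: FeatureParams | None = None
) -> dict[str, float]:
    """The 6 frequency-domain features of a single-channel window."""
    params = params or FeatureParams()
    x = _check_window(x, 8)
    f, p = _power_spectrum(x, sample_rate, params)
    ttp = float(p.sum())
    # a bin lying on the split (to float tolerance) counts as low band
    split = params.fr_band_split_hz * (1.0 + 1e-9)
    low = p[f <= split].sum()
    high = p[f > split].sum()
    if high > 0:
        fr = float(low / high)
    else:
        warnings.warn(
            "no spectral power above the FR band split; reporting FR sentinel 0",
            RuntimeWarning,
            stacklevel=2,
        )
        fr = 0.0
    if ttp > 0:
        mnf = float((f * p).sum() / ttp)
        mdf = float(f[np.searchsorted(np.cumsum(p), ttp / 2.0)])
    else:
        mnf = 0.0
        mdf = 0.0
    return {
        "TTP": ttp,
        "FR": fr,
        "MDF": mdf,
        "PKF": float(f[int(np.argmax(p))]),
        "MNF": mnf,
        "MNP": float(p.mean()),
    }


@dataclass
class FeatureMatrix:
    """n_windows x (17 * n_channels) feature table with labels.

    Column order is channel-major: all 17 features of channel 1, then of
    channel 2, etc., each block in :data:`FEATURE_NAMES` order.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    params: FeatureParams
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise InputError("values shape does not match feature_names")
        if self.labels.shape[0] != self.values.shape[0]:
            raise InputError("labels length must equal row count")

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        if self.subject_id:
            df.insert(0, "subject", self.subject_id)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, params: FeatureParams | None = None) -> "FeatureMatrix":
        subject = ""
        if "subject" in df.columns:
            subs = df["subject"].unique()
            subject = str(subs[0]) if len(subs) == 1 else ""
        names = [c for c in df.columns if c not in ("subject", "label", "window_id")]
        return cls(
            values=df[names].to_numpy(dtype=np.float64),
            feature_names=list(names),
            labels=df["label"].to_numpy(dtype=np.int64),
            params=params or FeatureParams(),
            subject_id=subject,
        )


def feature_columns(n_channels: int) -> list[str]:
    """Canonical column names ``ch1_MAV .. chK_MNP``."""
    return [f"ch{k + 1}_{name}" for k in range(n_channels) for name in FEATURE_NAMES]


def featurize(ws: WindowSet, params: FeatureParams | None = None) -> FeatureMatrix:
    """Compute the full feature matrix of a window set.

    Row i concatenates, channel by channel, the 17 features of window i.
    """
    params = params or FeatureParams()
    if len(ws) == 0:
        raise InputError("empty WindowSet")
    n, k = len(ws), ws.n_channels
    values = np.empty((n, 17 * k))
    for i in range(n):
        try:
            row = []
            for ch in range(k):
                x = ws.windows[i, ch]
                td = time_domain_features(x, params)
                fd = frequency_domain_features(x, ws.sample_rate, params)
                row.extend(td[name] for name in TIME_FEATURES)
                row.extend(fd[name] for name in FREQ_FEATURES)
            values[i] = row
        except InputError as exc:
            raise InputError(f"window {i}: {exc}") from exc
    return FeatureMatrix(
        values=values,
        feature_names=feature_columns(k),
        labels=ws.labels.copy(),
        params=params,
        subject_id=ws.subject_id,
    )
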