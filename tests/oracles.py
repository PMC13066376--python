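"""Independent naive reference implementations used to cross-check the
package.  Everything here is written per-definition with explicit loops or
direct formulas, deliberately avoiding the code paths under test."""

import math

import numpy as np


def naive_time_features(x, zc_threshold=0.0, wamp_threshold=0.01,
                        myop_threshold=0.016, log_epsilon=1e-12):
    """Loop-based time-domain feature definitions."""
    x = list(map(float, x))
    w = len(x)
    mean = sum(x) / w
    mav = sum(abs(v) for v in x) / w
    var = sum((v - mean) ** 2 for v in x) / (w - 1)
    d = [x[i + 1] - x[i] for i in range(w - 1)]
    dasdv = math.sqrt(sum(v**2 for v in d) / (w - 1))
    wl = sum(abs(v) for v in d)
    iemg = sum(abs(v) for v in x)
    logd = math.exp(sum(math.log(abs(v) + log_epsilon) for v in x) / w)
    rms = math.sqrt(sum(v**2 for v in x) / w)
    aac = wl / (w - 1)
    zc = sum(
        1
        for i in range(w - 1)
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= zc_threshold
    )
    wamp = sum(1 for v in d if abs(v) >= wamp_threshold)
    myop = sum(1 for v in x if abs(v) >= myop_threshold) / w
    return {
        "MAV": mav, "VAR": var, "DASDV": dasdv, "WL": wl, "IEMG": iemg,
        "LOG": logd, "RMS": rms, "AAC": aac, "ZC": float(zc),
        "WAMP": float(wamp), "MYOP": myop,
    }


def naive_one_sided_spectrum(x, fs):
    """Direct-DFT one-sided power spectrum with sum(P) == mean(x^2).

    Computed in extended precision so the O(n^2) direct sum stays well
    below the 1e-9 comparison tolerance.
    """
    x = np.asarray(x, dtype=np.longdouble)
    w = x.size
    n = np.arange(w, dtype=np.longdouble)
    n_bins = w // 2 + 1
    freqs = np.arange(n_bins) * fs / w
    power = np.empty(n_bins)
    for k in range(n_bins):
        phase = -2 * np.pi * k * n / w
        re = np.sum(x * np.cos(phase))
        im = np.sum(x * np.sin(phase))
        p = (re**2 + im**2) / np.longdouble(w) ** 2
        if 0 < k < w / 2:  # double everything except DC and Nyquist
            p *= 2
        power[k] = float(p)
    return freqs, power


def naive_freq_features(x, fs, split_hz=250.0):
    freqs, power = naive_one_sided_spectrum(x, fs)
    ttp = float(power.sum())
    split = split_hz * (1.0 + 1e-9)  # boundary bin belongs to the low band
    low = float(power[freqs <= split].sum())
    high = float(power[freqs > split].sum())
    fr = low / high if high > 0 else 0.0
    if ttp > 0:
        mnf = float((freqs * power).sum() / ttp)
        cum = 0.0
        mdf = 0.0
        for f, p in zip(freqs, power):
            cum += p
            if cum >= ttp / 2:
                mdf = float(f)
                break
        pkf = float(freqs[int(np.argmax(power))])
    else:
        mnf = mdf = pkf = 0.0
    return {
        "TTP": ttp, "FR": fr, "MDF": mdf, "PKF": pkf, "MNF": mnf,
        "MNP": float(power.mean()),
    }


def enumerate_window_starts(length, w, s):
    """Brute-force list of all valid window start offsets."""
    starts = []
    pos = 0
    while pos + w <= length:
        starts.append(pos)
        pos += s
    return starts


def naive_fused_argmax(z, m, class_order):
    """Exhaustive search of the largest elementwise product."""
    best_cls, best_val = None, -1.0
    for cls, zi, mi in zip(class_order, z, m):
        val = zi * mi
        if val > best_val:  # strict: earlier (lower) class wins ties
            best_val = val
            best_cls = cls
    return best_cls


def naive_paired_t(a, b):
    """Closed-form paired t statistic and two-tailed p-value."""
    from scipy.stats import t as t_dist

    d = [ai - bi for ai, bi in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
    t_stat = mean / (sd / math.sqrt(n))
    p = 2 * t_dist.sf(abs(t_stat), n - 1)
    return t_stat, p


def naive_confusion(y_true, y_pred, class_order):
    idx = {c: i for i, c in enumerate(class_order)}
    n = len(class_order)
    counts = [[0] * n for _ in range(n)]
    for t, p in zip(y_true, y_pred):
        counts[idx[t]][idx[p]] += 1
    return np.array(counts)
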