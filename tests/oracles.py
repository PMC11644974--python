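"""Independent brute-force implementations of the window features.

These deliberately avoid the package's vectorised code paths: plain Python
loops, hand-rolled quantile interpolation, an explicit DFT matrix instead of
rfft, and scipy.stats.pearsonr for correlations. They define the expected
values the production implementations are checked against.
"""

import math

import numpy as np
from scipy import stats


def oracle_statistical(x, quantiles=(0.25, 0.75)):
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    srt = sorted(x)
    if m2 == 0:
        skew = kurt = 0.0
    else:
        g1 = m3 / m2 ** 1.5
        g2 = m4 / m2 ** 2 - 3.0
        skew = math.sqrt(n * (n - 1)) / (n - 2) * g1
        kurt = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))

    def _quantile(q):
        h = (n - 1) * q
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

    out = {
        "mean": mean,
        "std": sd,
        "median": _quantile(0.5),
        "skew": skew,
        "kurtosis": kurt,
        "min": srt[0],
        "max": srt[-1],
    }
    for q in quantiles:
        out[f"q{100 * q:g}"] = _quantile(q)
    return out


_DFT_CACHE = {}


def _dft_matrix(n):
    if n not in _DFT_CACHE:
        k = np.arange(n // 2 + 1)
        j = np.arange(n)
        _DFT_CACHE[n] = np.exp(-2j * np.pi * np.outer(k, j) / n)
    return _DFT_CACHE[n]


def _dft_power(xc):
    """One-sided power spectrum via an explicit DFT matrix."""
    F = _dft_matrix(len(xc)) @ np.asarray(xc, dtype=float)
    return (F * F.conj()).real


def oracle_frequency(x, rate=60.0):
    x = [float(v) for v in x]
    n = len(x)
    if max(x) == min(x):
        return {k: 0.0 for k in ("energy", "entropy", "centroid", "bandwidth", "fmax")}
    mean = sum(x) / n
    P = _dft_power([v - mean for v in x])
    freqs = [k * rate / n for k in range(n // 2 + 1)]
    tot = float(sum(P))
    p = [v / tot for v in P]
    entropy = -sum(v * math.log(v) for v in p if v > 0)
    centroid = sum(f * v for f, v in zip(freqs, p))
    bandwidth = math.sqrt(sum((f - centroid) ** 2 * v for f, v in zip(freqs, p)))
    fmax = freqs[int(np.argmax(P))]
    return {
        "energy": tot,
        "entropy": entropy,
        "centroid": centroid,
        "bandwidth": bandwidth,
        "fmax": fmax,
    }


def oracle_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(stats.pearsonr(x, y)[0])


def oracle_axis_sum_mean(wx, wy, wz):
    vals = [float(a) + float(b) + float(c) for a, b, c in zip(wx, wy, wz)]
    return sum(vals) / len(vals)


def oracle_mean_diff(wa, wb):
    vals = [float(a) - float(b) for a, b in zip(wa, wb)]
    return sum(vals) / len(vals)


def oracle_loc_sum_mean(series_by_loc):
    n = len(next(iter(series_by_loc)))
    total = 0.0
    for i in range(n):
        total += sum(float(s[i]) for s in series_by_loc)
    return total / n
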