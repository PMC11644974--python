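"""Windowed feature extraction in five groups.

Every 2-s window of every derived channel yields *statistical* (moments,
quantiles, extremes) and *frequency* (spectral energy, entropy, centroid,
bandwidth, peak frequency) features; across axes and sensor locations the
*summary* (means of sums), *difference* (means of differences) and
*correlation* (Pearson) groups capture the joint structure. Tilt channels
(roll/pitch) participate in the time-domain groups only.

The formulas implemented here are normative for this package:

- sd uses the n-1 denominator; skewness is the adjusted Fisher-Pearson
  coefficient and kurtosis is bias-corrected excess kurtosis, both 0 by
  convention on constant windows;
- the spectrum is the one-sided periodogram of the mean-removed,
  rectangular-windowed samples, P(f) = |rfft(x - mean x)|^2; energy = sum P,
  entropy = -sum p ln p with p = P / sum P, centroid = sum f P / sum P,
  bandwidth = sqrt(sum (f - centroid)^2 P / sum P), fmax = argmax_f P(f);
  constant windows return all five as 0;
- Pearson correlations of zero-variance pairs are 0 by convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import (
    DESCRIPTOR_LEVELS,
    META_COLUMNS,
    FeatureTable,
    ValidationError,
)
from .segmentation import UNASSIGNED

__all__ = [
    "AXIS_FAMILIES",
    "SCALAR_CHANNELS",
    "ALL_CHANNELS",
    "FeatureConfig",
    "statistical_features",
    "frequency_features",
    "summary_features",
    "difference_features",
    "correlation_features",
    "build_feature_matrix",
]

AXES = ("x", "y", "z")

#: XYZ signal families, in canonical order.
AXIS_FAMILIES = {
    "acc": ("acc_x", "acc_y", "acc_z"),
    "acc_lp": ("acc_lp_x", "acc_lp_y", "acc_lp_z"),
    "acc_hp": ("acc_hp_x", "acc_hp_y", "acc_hp_z"),
    "gyro": ("gyro_x", "gyro_y", "gyro_z"),
    "mag": ("mag_x", "mag_y", "mag_z"),
}

#: Single-channel signals (norms and tilt angles).
SCALAR_CHANNELS = ("norm", "norm_lp", "norm_hp", "roll", "pitch")

#: Tilt channels stay out of the frequency group (time-domain only).
TIME_DOMAIN_ONLY = ("roll", "pitch")

ALL_CHANNELS = tuple(
    ch for fam in AXIS_FAMILIES.values() for ch in fam
) + SCALAR_CHANNELS


@dataclass(frozen=True)
class FeatureConfig:
    quantiles: tuple = (0.25, 0.75)
    spectral_estimator: str = "periodogram"  # or "welch"
    entropy_base: str = "e"  # "e" or "2"
    signals_included: tuple = ALL_CHANNELS
    sensor_set: tuple = ("trunk_a", "trunk_b", "leg_left", "leg_right")
    cross_modal_correlations: bool = False

    def __post_init__(self):
        if not self.sensor_set:
            raise ValidationError("sensor_set must be non-empty")
        if any(not 0 < q < 1 for q in self.quantiles):
            raise ValidationError("quantiles must lie in (0, 1)")
        if self.spectral_estimator not in ("periodogram", "welch"):
            raise ValidationError("spectral_estimator must be periodogram|welch")
        if self.entropy_base not in ("e", "2"):
            raise ValidationError("entropy_base must be 'e' or '2'")


def _qname(q: float) -> str:
    return f"q{100 * q:g}"


# ---------------------------------------------------------------------------
# Per-channel groups (vectorised over windows: W has shape (n_windows, n))

def statistical_features(W: np.ndarray, quantiles=(0.25, 0.75)) -> dict:
    """Distributional descriptors per window (rows of ``W``)."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n = W.shape[1]
    if n < 2:
        raise ValidationError("need at least 2 samples per window")
    mean = W.mean(axis=1)
    sd = W.std(axis=1, ddof=1)
    s_pop = W.std(axis=1)
    dev = W - mean[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        m2 = (dev ** 2).mean(axis=1)
        m3 = (dev ** 3).mean(axis=1)
        m4 = (dev ** 4).mean(axis=1)
        g1 = m3 / m2 ** 1.5
        g2 = m4 / m2 ** 2 - 3.0
        skew = np.sqrt(n * (n - 1)) / (n - 2) * g1 if n > 2 else g1
        kurt = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3)) if n > 3 else g2
    const = s_pop == 0
    skew = np.where(const, 0.0, skew)
    kurt = np.where(const, 0.0, kurt)
    out = {
        "mean": mean,
        "std": sd,
        "median": np.median(W, axis=1),
        "skew": skew,
        "kurtosis": kurt,
        "min": W.min(axis=1),
        "max": W.max(axis=1),
    }
    for q in quantiles:
        out[_qname(q)] = np.quantile(W, q, axis=1)
    return out


def frequency_features(W: np.ndarray, rate: float = 60.0,
                       estimator: str = "periodogram",
                       entropy_base: str = "e") -> dict:
    """Spectral descriptors of the mean-removed window."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    Xc = W - W.mean(axis=1, keepdims=True)
    if estimator == "periodogram":
        F = np.fft.rfft(Xc, axis=1)
        P = (F.real ** 2 + F.imag ** 2)
        freqs = np.fft.rfftfreq(W.shape[1], d=1.0 / rate)
    else:  # welch
        freqs, P = sps.welch(Xc, fs=rate, nperseg=min(W.shape[1], 64), axis=1)
    const = W.max(axis=1) == W.min(axis=1)
    tot = P.sum(axis=1)
    safe = np.where(tot > 0, tot, 1.0)
    p = P / safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -(p * logp).sum(axis=1)
    if entropy_base == "2":
        entropy = entropy / np.log(2.0)
    centroid = (p * freqs[None, :]).sum(axis=1)
    bandwidth = np.sqrt(
        np.maximum((p * (freqs[None, :] - centroid[:, None]) ** 2).sum(axis=1), 0.0)
    )
    fmax = freqs[np.argmax(P, axis=1)]
    zero = const | (tot <= 0)
    z = lambda a: np.where(zero, 0.0, a)  # noqa: E731
    return {
        "energy": z(tot),
        "entropy": z(entropy),
        "centroid": z(centroid),
        "bandwidth": z(bandwidth),
        "fmax": z(fmax),
    }


# ---------------------------------------------------------------------------
# Cross-axis / cross-location groups

def _pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r; 0 where either row has zero variance."""
    mA = A.mean(axis=1)
    mB = B.mean(axis=1)
    cov = (A * B).mean(axis=1) - mA * mB
    sA = A.std(axis=1)
    sB = B.std(axis=1)
    denom = sA * sB
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def summary_features(windows_by_channel: dict, cfg: FeatureConfig) -> dict:
    """Means of axis-sums (per location) and location-sums (per channel).

    ``windows_by_channel`` maps (location, channel) -> (n_windows, n) array.
    Returns descriptor-tuple -> value-vector.
    """
    locs = [l for l in sorted(cfg.sensor_set)]
    out = {}
    for loc in locs:
        for fam, chans in AXIS_FAMILIES.items():
            if not all(ch in cfg.signals_included for ch in chans):
                continue
            s = sum(windows_by_channel[(loc, ch)].mean(axis=1) for ch in chans)
            out[(loc, fam, "summary", "axis_sum_mean")] = s
    for ch in _loc_pairable_channels(cfg):
        s = sum(windows_by_channel[(loc, ch)].mean(axis=1) for loc in locs)
        out[("combined", ch, "summary", "loc_sum_mean")] = s
    return out


def difference_features(windows_by_channel: dict, cfg: FeatureConfig) -> dict:
    """Window means of axis differences and location differences."""
    locs = sorted(cfg.sensor_set)
    out = {}
    for loc in locs:
        for fam, chans in AXIS_FAMILIES.items():
            if not all(ch in cfg.signals_included for ch in chans):
                continue
            means = {ax: windows_by_channel[(loc, ch)].mean(axis=1)
                     for ax, ch in zip(AXES, chans)}
            for ai, aj in itertools.combinations(AXES, 2):
                out[(loc, fam, "difference", f"mean_diff_{ai}_{aj}")] = (
                    means[ai] - means[aj]
                )
    for ch in _loc_pairable_channels(cfg):
        for la, lb in itertools.combinations(locs, 2):
            out[("combined", ch, "difference", f"mean_diff_{la}_{lb}")] = (
                windows_by_channel[(la, ch)].mean(axis=1)
                - windows_by_channel[(lb, ch)].mean(axis=1)
            )
    return out


def correlation_features(windows_by_channel: dict, cfg: FeatureConfig) -> dict:
    """Pearson correlations across axes and across locations."""
    locs = sorted(cfg.sensor_set)
    out = {}
    for loc in locs:
        for fam, chans in AXIS_FAMILIES.items():
            if not all(ch in cfg.signals_included for ch in chans):
                continue
            for (ai, ci), (aj, cj) in itertools.combinations(zip(AXES, chans), 2):
                out[(loc, fam, "correlation", f"corr_{ai}_{aj}")] = _pearson(
                    windows_by_channel[(loc, ci)], windows_by_channel[(loc, cj)]
                )
        if cfg.cross_modal_correlations:
            fams = [f for f, chans in AXIS_FAMILIES.items()
                    if all(ch in cfg.signals_included for ch in chans)]
            for fa, fb in itertools.combinations(fams, 2):
                for ax in AXES:
                    ca = AXIS_FAMILIES[fa][AXES.index(ax)]
                    cb = AXIS_FAMILIES[fb][AXES.index(ax)]
                    out[(loc, f"{fa}~{fb}", "correlation", f"xmod_corr_{ax}")] = (
                        _pearson(windows_by_channel[(loc, ca)],
                                 windows_by_channel[(loc, cb)])
                    )
    for ch in _loc_pairable_channels(cfg):
        for la, lb in itertools.combinations(locs, 2):
            out[("combined", ch, "correlation", f"corr_{la}_{lb}")] = _pearson(
                windows_by_channel[(la, ch)], windows_by_channel[(lb, ch)]
            )
    return out


def _loc_pairable_channels(cfg: FeatureConfig):
    """Channels entering location sums/differences/correlations, in canonical
    order: the axis-family channels followed by the scalar channels."""
    chans = [ch for fam in AXIS_FAMILIES.values() for ch in fam
             if all(c in cfg.signals_included for c in fam)]
    chans += [ch for ch in SCALAR_CHANNELS if ch in cfg.signals_included]
    return chans


# ---------------------------------------------------------------------------

def window_index_matrix(windows, t0: float, rate: float, length_s: float) -> np.ndarray:
    """(n_windows, n_len) sample indices for a uniform grid starting at t0."""
    n_len = int(round(length_s * rate))
    starts = np.asarray([int(round((w.start_s - t0) * rate)) for w in windows])
    return starts[:, None] + np.arange(n_len)[None, :]


def build_feature_matrix(derived: dict, windows, cfg: FeatureConfig,
                         infant_id: str, session_id: str,
                         rate: float = 60.0, length_s: float = 2.0) -> FeatureTable:
    """One row per labelled window, columns over all five feature groups.

    ``derived`` maps location -> :class:`~imuposture.preprocess.DerivedSignals`
    covering at least ``cfg.sensor_set``. Windows labelled UNASSIGNED are
    skipped; rows that end up with missing values (e.g. undefined tilt) are
    dropped. Column order is canonical, so the result is independent of the
    order sensors were loaded in.
    """
    missing = [loc for loc in cfg.sensor_set if loc not in derived]
    if missing:
        raise ValidationError(f"sensor locations missing from session: {missing}")
    labelled = [w for w in windows if w.label != UNASSIGNED]

    locs = sorted(cfg.sensor_set)
    wbc = {}
    if labelled:
        for loc in locs:
            dsig = derived[loc]
            idx = window_index_matrix(labelled, dsig.timestamps[0], rate, length_s)
            if idx.min() < 0 or idx.max() >= dsig.timestamps.shape[0]:
                raise ValidationError(f"window outside recording at {loc}")
            for ch in cfg.signals_included:
                wbc[(loc, ch)] = dsig[ch][idx]
    else:
        n_len = int(round(length_s * rate))
        for loc in locs:
            for ch in cfg.signals_included:
                wbc[(loc, ch)] = np.empty((0, n_len))

    columns: list[tuple] = []
    data: list[np.ndarray] = []

    def _emit(desc: tuple, vec: np.ndarray) -> None:
        columns.append(desc)
        data.append(vec)

    for loc in locs:
        for ch in cfg.signals_included:
            for name, vec in statistical_features(
                wbc[(loc, ch)], cfg.quantiles
            ).items():
                _emit((loc, ch, "statistical", name), vec)
    for loc in locs:
        for ch in cfg.signals_included:
            if ch in TIME_DOMAIN_ONLY:
                continue
            for name, vec in frequency_features(
                wbc[(loc, ch)], rate, cfg.spectral_estimator, cfg.entropy_base
            ).items():
                _emit((loc, ch, "frequency", name), vec)
    for desc, vec in summary_features(wbc, cfg).items():
        _emit(desc, vec)
    for desc, vec in difference_features(wbc, cfg).items():
        _emit(desc, vec)
    for desc, vec in correlation_features(wbc, cfg).items():
        _emit(desc, vec)

    col_index = pd.MultiIndex.from_tuples(columns, names=DESCRIPTOR_LEVELS)
    values = pd.DataFrame(
        np.column_stack(data) if data and labelled else
        np.empty((len(labelled), len(columns))),
        columns=col_index,
    )
    meta = pd.DataFrame(
        {
            "infant_id": [infant_id] * len(labelled),
            "session_id": [session_id] * len(labelled),
            "window_start": [w.start_s for w in labelled],
            "label": [w.label for w in labelled],
        },
        columns=list(META_COLUMNS),
    )
    keep = ~values.isna().any(axis=1).to_numpy()
    if not keep.all():
        values = values.loc[keep].reset_index(drop=True)
        meta = meta.loc[keep].reset_index(drop=True)
    return FeatureTable(values, meta)
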