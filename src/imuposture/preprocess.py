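"""Raw-recording cleanup and derived signals.

Recordings come in at a nominal 60 Hz (occasionally 40 Hz) with wireless
dropouts. The pipeline: cubic-spline gap filling onto a uniform grid,
polyphase resampling of 40 Hz streams to 60 Hz, artefact masking of displaced
stationary sensors (acceleration-magnitude variance below 1e-6 in 0.1-s
blocks), complementary low/high-pass decomposition of the accelerometer into
gravity (DC) and movement (AC) parts, Euclidean norms, accelerometer tilt
(roll/pitch), and clap-based estimation of the annotation-to-IMU delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io import SensorRecording, ValidationError

__all__ = [
    "PreprocessConfig",
    "DerivedSignals",
    "SyncError",
    "SyncWarning",
    "fill_gaps",
    "resample_to_target",
    "mask_artifacts",
    "decompose_acc",
    "roll_pitch",
    "estimate_sync_delay",
    "preprocess_recording",
]

GRAVITY = 9.81  # m/s^2


class SyncError(RuntimeError):
    """Clap-based synchronisation failed (no usable peak/clap matches)."""


class SyncWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Numeric preprocessing choices.

    The artefact threshold is applied, as printed in the protocol, to the
    sample variance of the acceleration magnitude in 0.1-s blocks. The LP/HP
    split uses a complementary design: the high-pass part is the residual of
    the low-pass filter, so acc_lp + acc_hp reconstructs the input exactly
    when the two cutoffs coincide.
    """

    target_rate: int = 60
    artifact_window_s: float = 0.1
    artifact_var_threshold: float = 1e-6
    lp_cutoff_hz: float = 1.0
    hp_cutoff_hz: float = 1.0
    filter_order: int = 4
    max_gap_s: float = 1.0
    clap_count_expected: int = 5

    def __post_init__(self):
        if self.artifact_window_s <= 0:
            raise ValidationError("artifact_window_s must be positive")
        nyq = self.target_rate / 2
        if not (0 < self.lp_cutoff_hz < nyq and 0 < self.hp_cutoff_hz < nyq):
            raise ValidationError("filter cutoffs must lie in (0, Nyquist)")


@dataclass
class DerivedSignals:
    """Per-location channel bank on the common 60 Hz time base."""

    location: str
    timestamps: np.ndarray
    channels: dict = field(default_factory=dict)  # name -> (T,) array
    artifact_mask: np.ndarray = None  # type: ignore[assignment]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


# ---------------------------------------------------------------------------

def _uniform_grid(t: np.ndarray, rate: int):
    t0 = t[0]
    n = int(round((t[-1] - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    idx = np.round((t - t0) * rate).astype(int)
    idx = np.clip(idx, 0, n - 1)
    return grid, idx


def fill_gaps(recording: SensorRecording, max_gap_s: float = 1.0) -> SensorRecording:
    """Place samples on a uniform grid and spline-interpolate missing ones.

    Observed samples are kept unchanged. Gaps longer than ``max_gap_s`` are
    still filled (so downstream filters see a continuous series) but flagged
    in the artefact mask instead of being trusted.
    """
    t = recording.timestamps
    if t.shape[0] < 4:
        raise ValidationError("need at least 4 samples for cubic-spline filling")
    rate = recording.nominal_rate
    grid, idx = _uniform_grid(t, rate)
    n = grid.shape[0]

    observed = np.zeros(n, dtype=bool)
    observed[idx] = True
    mask = np.zeros(n, dtype=bool)
    mask[idx] = recording.artifact_mask

    def _fill(block: np.ndarray) -> np.ndarray:
        out = np.empty((3, n))
        out[:, idx] = block
        if not observed.all():
            missing = ~observed
            cs = CubicSpline(t, block, axis=1)
            out[:, missing] = cs(grid[missing])
        return out

    acc = _fill(recording.acc)
    gyro = _fill(recording.gyro)
    mag = _fill(recording.mag)

    # flag over-long gaps
    if not observed.all():
        missing = ~observed
        edges = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if (hi - lo) / rate > max_gap_s:
                mask[lo:hi] = True

    return SensorRecording(
        location=recording.location,
        timestamps=grid,
        acc=acc,
        gyro=gyro,
        mag=mag,
        nominal_rate=rate,
        artifact_mask=mask,
    )


def resample_to_target(recording: SensorRecording,
                       cfg: PreprocessConfig = PreprocessConfig()) -> SensorRecording:
    """Bring a recording to the 60 Hz analysis rate.

    Already-at-rate input is returned unchanged; 40 Hz input is polyphase
    resampled (up 3, down 2) with the built-in anti-aliasing filter.
    """
    if recording.nominal_rate == cfg.target_rate:
        return recording
    if recording.nominal_rate != 40 or cfg.target_rate != 60:
        raise ValidationError(
            f"unsupported resampling {recording.nominal_rate} -> {cfg.target_rate} Hz"
        )
    up, down = 3, 2

    def _res(block: np.ndarray) -> np.ndarray:
        # remove the per-channel mean first so DC survives the anti-alias
        # filter's passband ripple exactly
        m = block.mean(axis=1, keepdims=True)
        return sps.resample_poly(block - m, up, down, axis=1, padtype="line") + m

    n_new = int(np.ceil(recording.n_samples * up / down))
    t0 = recording.timestamps[0]
    grid = t0 + np.arange(n_new) / cfg.target_rate
    src = np.minimum((np.arange(n_new) * down) // up, recording.n_samples - 1)
    return SensorRecording(
        location=recording.location,
        timestamps=grid,
        acc=_res(recording.acc)[:, :n_new],
        gyro=_res(recording.gyro)[:, :n_new],
        mag=_res(recording.mag)[:, :n_new],
        nominal_rate=cfg.target_rate,
        artifact_mask=recording.artifact_mask[src],
    )


def mask_artifacts(recording: SensorRecording,
                   cfg: PreprocessConfig = PreprocessConfig()) -> SensorRecording:
    """Mask spans where the sensor lay still after being displaced.

    The acceleration magnitude's sample variance is computed in non-overlapping
    0.1-s blocks (last partial block dropped); blocks below the threshold are
    marked as artefacts. Masking is monotone in the threshold and invariant to
    adding a constant to every acceleration channel.
    """
    out = recording.copy()
    n_block = int(round(cfg.artifact_window_s * recording.nominal_rate))
    if n_block < 2 or recording.n_samples < n_block:
        return out
    mag = np.linalg.norm(recording.acc, axis=0)
    n_full = (mag.shape[0] // n_block) * n_block
    blocks = mag[:n_full].reshape(-1, n_block)
    var = blocks.var(axis=1, ddof=1)
    low = var < cfg.artifact_var_threshold
    out.artifact_mask[:n_full] |= np.repeat(low, n_block)
    return out


def _butter_lp(x: np.ndarray, cutoff: float, rate: int, order: int) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    ntaps = 2 * sos.shape[0] + 1
    padlen = min(x.shape[-1] - 1, 3 * ntaps)
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def decompose_acc(recording: SensorRecording,
                  cfg: PreprocessConfig = PreprocessConfig()) -> DerivedSignals:
    """Split acceleration into gravity (LP/DC) and movement (HP/AC) parts.

    Zero-phase Butterworth low-pass gives acc_lp; acc_hp is the residual of a
    low-pass at the HP cutoff, so DC is removed exactly and the two parts are
    complementary when the cutoffs coincide. Euclidean norms of the raw, LP
    and HP triples plus tilt angles complete the channel bank.
    """
    rate = recording.nominal_rate
    nyq = rate / 2
    if cfg.lp_cutoff_hz >= nyq or cfg.hp_cutoff_hz >= nyq:
        raise ValidationError("cutoff at or above Nyquist")
    acc = recording.acc
    acc_lp = _butter_lp(acc, cfg.lp_cutoff_hz, rate, cfg.filter_order)
    acc_hp = acc - _butter_lp(acc, cfg.hp_cutoff_hz, rate, cfg.filter_order)
    roll, pitch = roll_pitch(acc_lp)
    channels = {}
    for i, ax in enumerate("xyz"):
        channels[f"acc_{ax}"] = acc[i]
        channels[f"acc_lp_{ax}"] = acc_lp[i]
        channels[f"acc_hp_{ax}"] = acc_hp[i]
        channels[f"gyro_{ax}"] = recording.gyro[i]
        channels[f"mag_{ax}"] = recording.mag[i]
    channels["norm"] = np.linalg.norm(acc, axis=0)
    channels["norm_lp"] = np.linalg.norm(acc_lp, axis=0)
    channels["norm_hp"] = np.linalg.norm(acc_hp, axis=0)
    channels["roll"] = roll
    channels["pitch"] = pitch
    return DerivedSignals(
        location=recording.location,
        timestamps=recording.timestamps,
        channels=channels,
        artifact_mask=recording.artifact_mask.copy(),
    )


def roll_pitch(acc_lp: np.ndarray):
    """Tilt angles from the gravity direction (aerospace convention).

    roll = atan2(a_y, a_z); pitch = atan2(-a_x, sqrt(a_y^2 + a_z^2)).
    Both are invariant to positive rescaling of the input; zero-norm samples
    propagate NaN so the affected windows are rejected later.
    """
    ax, ay, az = np.asarray(acc_lp, dtype=float)
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    with np.errstate(invalid="ignore"):
        roll = np.arctan2(ay, az)
        pitch = np.arctan2(-ax, np.hypot(ay, az))
    bad = norm == 0
    if np.any(bad):
        roll = np.where(bad, np.nan, roll)
        pitch = np.where(bad, np.nan, pitch)
    return roll, pitch


# ---------------------------------------------------------------------------
# Clap synchronisation

def _detect_clap_peaks(avg_norm: np.ndarray, t: np.ndarray, rate: float):
    """Clap spikes: prominent peaks of the baseline-removed average norm.

    The floor is 5x the MAD of the signal; because arm movement also produces
    small peaks, the threshold is additionally tied to the largest prominence
    present, which claps dominate by an order of magnitude.
    """
    baseline = np.median(avg_norm)
    resid = avg_norm - baseline
    mad = np.median(np.abs(resid - np.median(resid)))
    floor = 5.0 * mad if mad > 0 else 0.5
    peaks, props = sps.find_peaks(
        resid, prominence=floor, distance=max(int(0.25 * rate), 1)
    )
    if peaks.size:
        thresh = max(floor, 0.2 * props["prominences"].max())
        keep = props["prominences"] >= thresh
        peaks = peaks[keep]
    return t[peaks]


def estimate_sync_delay(caregiver_norms, timestamps, clap_times_audio,
                        cfg: PreprocessConfig = PreprocessConfig()) -> float:
    """Delay (seconds) of IMU time relative to the audio annotations.

    The caregiver claps a known number of times at task start; spikes are
    detected in the average of both arm-norm channels (prominence 5x the MAD
    of the baseline-removed signal) and matched to the annotated clap times
    by the constant offset supported by the most clap/peak pairs. Returns the
    median of (IMU peak - audio time) over matched pairs; adding it to
    annotation times moves them onto the IMU clock.
    """
    clap_times_audio = np.asarray(clap_times_audio, dtype=float)
    if clap_times_audio.size == 0:
        raise SyncError("no annotated clap times")
    norms = np.asarray(caregiver_norms, dtype=float)
    if norms.ndim != 2 or norms.shape[0] != 2:
        raise ValidationError("caregiver_norms must be two arm-norm series (2, T)")
    t = np.asarray(timestamps, dtype=float)
    rate = (t.shape[0] - 1) / (t[-1] - t[0]) if t.shape[0] > 1 else 60.0
    peak_times = _detect_clap_peaks(norms.mean(axis=0), t, rate)
    if peak_times.size == 0:
        raise SyncError("no clap-like peaks detected in caregiver arm norms")
    if peak_times.size != cfg.clap_count_expected:
        warnings.warn(
            f"detected {peak_times.size} clap peaks, expected "
            f"{cfg.clap_count_expected}; using best-effort ordered matching",
            SyncWarning,
            stacklevel=2,
        )
    # tolerance: half the smallest clap spacing, capped at 0.5 s
    if clap_times_audio.size > 1:
        tol = min(0.5, 0.5 * np.min(np.diff(np.sort(clap_times_audio))))
    else:
        tol = 0.5
    best = None
    for p in peak_times:
        for c in clap_times_audio:
            delta = p - c
            diffs = []
            for cc in clap_times_audio:
                err = np.abs(peak_times - (cc + delta))
                j = int(np.argmin(err))
                if err[j] <= tol:
                    diffs.append(peak_times[j] - cc)
            if diffs:
                spread = float(np.median(np.abs(np.asarray(diffs) - np.median(diffs))))
                key = (-len(diffs), spread)
                if best is None or key < best[0]:
                    best = (key, diffs)
    if best is None:
        raise SyncError("could not match any detected peak to an annotated clap")
    return float(np.median(best[1]))


# ---------------------------------------------------------------------------

def preprocess_recording(recording: SensorRecording,
                         cfg: PreprocessConfig = PreprocessConfig()) -> DerivedSignals:
    """fill gaps -> resample to 60 Hz -> artefact mask -> derived channels."""
    rec = fill_gaps(recording, cfg.max_gap_s)
    rec = resample_to_target(rec, cfg)
    rec = mask_artifacts(rec, cfg)
    return decompose_acc(rec, cfg)
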