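"""Synthetic infant play-session generator.

Emits sessions in exactly the package's file formats so every pipeline stage
is exercisable without the study dataset. A session is a Markov chain over
the five static positions with log-normally distributed dwell times and
unlabelled transition gaps. Each position fixes, per sensor location, the
direction gravity takes in the sensor frame; the accelerometer reads
g x (that direction, slowly jittered) plus band-limited (2-15 Hz) movement
noise, the gyroscope reads the angular velocity of the orientation path plus
white noise, and the magnetometer reads a fixed world field rotated into the
sensor frame plus noise. Wireless dropouts, occasional 40 Hz sessions,
displaced-sensor (constant) artefact spans, caregiver clap spikes and a true
annotation-to-IMU delay complete the picture; annotations are written on the
audio clock, shifted by the true delay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io import (
    LOCATIONS,
    TASKS,
    AGE_POINTS,
    AnnotationTrack,
    ValidationError,
    write_annotations,
    write_manifest,
)
from .preprocess import GRAVITY
from .segmentation import CLASSES, CLASS_MAP

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PRESETS",
    "simulate_session",
    "simulate_dataset",
    "make_benchmark_suite",
    "simulate_clap_track",
]

#: raw labels per static class (inverse of the class map), canonical order
_RAW_OF_CLASS = {
    cls: tuple(raw for raw, c in CLASS_MAP.items() if c == cls) for cls in CLASSES
}

#: per-class sensor-frame gravity direction before per-location adjustment
_BASE_DIR = {
    "Supine": (0.0, 0.0, 1.0),
    "Prone": (0.0, 0.0, -1.0),
    "Sitting": (1.0, 0.0, 0.0),
    "Upright": (0.0, 1.0, 0.0),
    "Hands and Knees": (0.6, 0.0, -0.8),
}

#: fixed per-location twist (rad, about the y then x axis) so the same
#: position looks different on different body parts
_LOC_TWIST = {
    "trunk_a": 0.0,
    "trunk_b": 0.15,
    "leg_left": 0.35,
    "leg_right": -0.35,
    "arm_left": 0.55,
    "arm_right": -0.55,
}


def _rot_y(v, a):
    c, s = np.cos(a), np.sin(a)
    x, y, z = v
    return np.array([c * x + s * z, y, -s * x + c * z])


def _rot_x(v, a):
    c, s = np.cos(a), np.sin(a)
    x, y, z = v
    return np.array([x, c * y - s * z, s * y + c * z])


def default_orientations(base_dirs=None) -> dict:
    """(class, location) -> unit gravity direction in the sensor frame."""
    base_dirs = dict(_BASE_DIR if base_dirs is None else base_dirs)
    out = {}
    for cls, d in base_dirs.items():
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        for loc, tw in _LOC_TWIST.items():
            v = _rot_x(_rot_y(d, tw), tw / 2)
            out[(cls, loc)] = v / np.linalg.norm(v)
    return out


@dataclass(frozen=True)
class SimulationConfig:
    n_infants: int = 20
    sessions_per_infant: int = 3
    session_s: float = 300.0
    #: log-normal dwell-time means per class (s) and common log-sd
    dwell_mean_s: dict = field(default_factory=lambda: {
        "Sitting": 25.0, "Upright": 15.0, "Supine": 25.0,
        "Prone": 20.0, "Hands and Knees": 10.0,
    })
    dwell_log_sd: float = 0.4
    transition_gap_s: float = 1.5
    #: (class, location) -> unit vector; None -> defaults
    orientations: dict | None = None
    #: band-limited movement-noise sd per class (m/s^2)
    movement_noise_sd: dict = field(default_factory=lambda: {
        "Sitting": 0.3, "Upright": 0.4, "Supine": 0.2,
        "Prone": 0.25, "Hands and Knees": 0.5,
    })
    transition_noise_sd: float = 0.6
    noise_band_hz: tuple = (2.0, 15.0)
    orientation_jitter_sd: float = 0.02   # rad, slow wander
    mag_field: tuple = (22.0, 5.0, -41.0)  # world frame, arbitrary units
    mag_noise_sd: float = 0.4
    gyro_noise_sd: float = 0.05           # rad/s
    dropout_prob: float = 0.3             # per session
    dropout_count_mean: float = 2.0
    dropout_max_gap_s: float = 0.5
    rate_switch_prob: float = 0.1         # session recorded at 40 Hz
    artifact_span_prob: float = 0.0       # displaced-sensor constant span
    artifact_span_s: float = 3.0
    clap_times_audio: tuple = (2.0, 3.0, 4.0, 5.0, 6.0)
    clap_amplitude: float = 25.0
    sync_delay_range_s: tuple = (-2.0, 2.0)
    locations: tuple = LOCATIONS
    seed: int = 0

    def __post_init__(self):
        for cls, m in self.dwell_mean_s.items():
            if m <= 2.0:
                raise ValidationError(
                    f"dwell mean for {cls} must exceed the 2-s window length"
                )
        if self.session_s <= 10:
            raise ValidationError("session too short to be useful")

    def resolved_orientations(self) -> dict:
        ori = self.orientations if self.orientations is not None else default_orientations()
        out = {}
        for key, v in ori.items():
            v = np.asarray(v, dtype=float)
            n = np.linalg.norm(v)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValidationError(f"orientation for {key} is not unit-norm")
            out[key] = v / n
        return out


@dataclass
class GroundTruth:
    session_id: str
    intervals: list      # (start_s, end_s, class) on the IMU clock
    sync_delay: float
    rate: int
    artifact_spans: dict  # location -> list of (start_s, end_s)

    def to_json(self) -> str:
        return json.dumps(
            {
                "session_id": self.session_id,
                "intervals": [[s, e, c] for s, e, c in self.intervals],
                "sync_delay": self.sync_delay,
                "rate": self.rate,
                "artifact_spans": {k: [list(x) for x in v]
                                   for k, v in self.artifact_spans.items()},
            },
            indent=1,
        )


# ---------------------------------------------------------------------------

def _position_sequence(cfg: SimulationConfig, rng) -> list:
    """(start, end, class) intervals separated by transition gaps."""
    classes = list(CLASSES)
    intervals = []
    t = 0.0
    cls = classes[rng.integers(len(classes))]
    while t < cfg.session_s:
        m = cfg.dwell_mean_s[cls]
        s = cfg.dwell_log_sd
        dwell = float(rng.lognormal(np.log(m) - s * s / 2.0, s))
        dwell = max(dwell, 0.5)
        end = min(t + dwell, cfg.session_s)
        intervals.append((t, end, cls))
        t = end + cfg.transition_gap_s
        others = [c for c in classes if c != cls]
        cls = others[rng.integers(len(others))]
    return intervals


def _slerp(a, b, frac):
    """Spherical interpolation between unit vectors for an array of fractions."""
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    if dot > 1 - 1e-10:
        return a[None, :] + frac[:, None] * (b - a)[None, :]
    omega = np.arccos(dot)
    if dot < -1 + 1e-10:
        # antipodal: go through an arbitrary perpendicular waypoint
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        first = _slerp(a, perp, np.clip(frac * 2, 0, 1))
        second = _slerp(perp, b, np.clip(frac * 2 - 1, 0, 1))
        return np.where(frac[:, None] < 0.5, first, second)
    sin = np.sin(omega)
    return (
        (np.sin((1 - frac) * omega) / sin)[:, None] * a[None, :]
        + (np.sin(frac * omega) / sin)[:, None] * b[None, :]
    )


def _orientation_path(cfg, intervals, loc, t, rng, ori):
    """Gravity direction per sample: class targets, slerp through gaps,
    plus a slow small-angle jitter."""
    n = t.shape[0]
    dirs = np.empty((n, 3))
    # fill per-interval
    for s, e, cls in intervals:
        sel = (t >= s) & (t < e)
        dirs[sel] = ori[(cls, loc)]
    # gaps: slerp between neighbouring targets
    bounds = [(0.0, intervals[0][0], None, intervals[0][2])]
    for (s0, e0, c0), (s1, e1, c1) in zip(intervals, intervals[1:]):
        bounds.append((e0, s1, c0, c1))
    bounds.append((intervals[-1][1], t[-1] + 1.0, intervals[-1][2], None))
    for gs, ge, c_prev, c_next in bounds:
        sel = (t >= gs) & (t < ge)
        if not sel.any():
            continue
        a = ori[(c_prev, loc)] if c_prev else ori[(c_next, loc)]
        b = ori[(c_next, loc)] if c_next else ori[(c_prev, loc)]
        frac = (t[sel] - gs) / max(ge - gs, 1e-9)
        seg = _slerp(np.asarray(a), np.asarray(b), frac)
        dirs[sel] = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    if cfg.orientation_jitter_sd > 0 and n > 30:
        rate = (n - 1) / (t[-1] - t[0])
        sos = sps.butter(2, 0.5, btype="low", fs=rate, output="sos")
        ang = sps.sosfiltfilt(sos, rng.standard_normal((2, n)), axis=1)
        sd = ang.std(axis=1, keepdims=True)
        ang = cfg.orientation_jitter_sd * ang / np.where(sd > 0, sd, 1.0)
        # two perpendicular tangent directions per sample
        ref = np.where(np.abs(dirs[:, 2:3]) < 0.9,
                       np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]]))
        e1 = np.cross(dirs, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(dirs, e1)
        dirs = dirs + ang[0][:, None] * e1 + ang[1][:, None] * e2
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs


def _bandlimited_noise(shape, rate, band, rng):
    lo, hi = band
    hi = min(hi, 0.45 * rate)
    x = rng.standard_normal(shape)
    sos = sps.butter(2, (lo, hi), btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _rotate_world_to_sensor(dirs: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Apply, per sample, the minimal rotation taking world-up to ``dirs``.

    Returns the world vector ``B`` expressed in each sensor frame, (n, 3).
    """
    a = np.array([0.0, 0.0, 1.0])
    c = dirs @ a  # cos angle
    v = np.cross(np.broadcast_to(a, dirs.shape), dirs)
    vxB = np.cross(v, np.broadcast_to(B, dirs.shape))
    vdB = v @ B
    denom = np.where(1 + c > 1e-8, 1 + c, 1.0)
    out = c[:, None] * B[None, :] + vxB + (vdB / denom)[:, None] * v
    flipped = np.array([B[0], -B[1], -B[2]])  # 180-deg about x
    out = np.where((1 + c <= 1e-8)[:, None], flipped[None, :], out)
    return out


def simulate_clap_track(cfg: SimulationConfig, rng, delay: float,
                        duration: float | None = None, rate: int = 60,
                        spurious_time: float | None = None):
    """Caregiver arm-norm channels with clap spikes at audio time + delay."""
    duration = cfg.session_s if duration is None else duration
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    norms = GRAVITY + 0.15 * _bandlimited_noise((2, n), rate, (0.5, 8.0), rng)
    spike_times = [c + delay for c in cfg.clap_times_audio]
    if spurious_time is not None:
        spike_times.append(spurious_time)
    for st in spike_times:
        i = int(round(st * rate))
        if 1 <= i < n - 1:
            norms[:, i] += cfg.clap_amplitude
            norms[:, i - 1] += 0.35 * cfg.clap_amplitude
            norms[:, i + 1] += 0.35 * cfg.clap_amplitude
    return t, norms


def _interval_noise_sd(cfg, intervals, t):
    sd = np.full(t.shape[0], cfg.transition_noise_sd)
    for s, e, cls in intervals:
        sel = (t >= s) & (t < e)
        sd[sel] = cfg.movement_noise_sd[cls]
    return sd


def simulate_session(cfg: SimulationConfig, infant_id: str, session_index: int,
                     rng, outdir) -> tuple:
    """Write one synthetic session to ``outdir``; return (manifest_path, truth).

    Same rng state (same seed path) gives byte-identical output files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ori = cfg.resolved_orientations()

    rate = 40 if rng.random() < cfg.rate_switch_prob else 60
    intervals = _position_sequence(cfg, rng)
    delay = float(rng.uniform(*cfg.sync_delay_range_s))
    n = int(round(cfg.session_s * rate)) + 1
    t = np.arange(n) / rate

    noise_sd = _interval_noise_sd(cfg, intervals, t)
    B = np.asarray(cfg.mag_field, dtype=float)

    task = TASKS[session_index % len(TASKS)]
    age = AGE_POINTS[session_index % len(AGE_POINTS)]
    session_id = f"{infant_id}_s{session_index}"
    sdir = outdir / session_id
    sdir.mkdir(parents=True, exist_ok=True)

    artifact_spans: dict = {}
    sensor_paths = {}
    for loc in cfg.locations:
        dirs = _orientation_path(cfg, intervals, loc, t, rng, ori)
        acc = GRAVITY * dirs.T + noise_sd[None, :] * _bandlimited_noise(
            (3, n), rate, cfg.noise_band_hz, rng
        )
        # angular velocity of the orientation path + white noise
        omega = np.zeros((3, n))
        d_next = np.cross(dirs[:-1], dirs[1:]) * rate
        omega[:, :-1] = d_next.T
        omega[:, -1] = omega[:, -2]
        gyro = omega + cfg.gyro_noise_sd * rng.standard_normal((3, n))
        mag = _rotate_world_to_sensor(dirs, B).T
        mag = mag + cfg.mag_noise_sd * rng.standard_normal((3, n))

        spans = []
        if cfg.artifact_span_prob > 0 and rng.random() < cfg.artifact_span_prob:
            s0 = float(rng.uniform(0, cfg.session_s - cfg.artifact_span_s))
            s1 = s0 + cfg.artifact_span_s
            sel = (t >= s0) & (t < s1)
            acc[:, sel] = acc[:, sel].mean(axis=1, keepdims=True) * 0 + np.array(
                [[0.3], [0.2], [GRAVITY]]
            )
            spans.append((s0, s1))
        artifact_spans[loc] = spans

        keep = np.ones(n, dtype=bool)
        if rng.random() < cfg.dropout_prob:
            for _ in range(rng.poisson(cfg.dropout_count_mean)):
                glen = int(rng.uniform(2, max(cfg.dropout_max_gap_s * rate, 3)))
                g0 = int(rng.uniform(1, n - glen - 1))
                keep[g0:g0 + glen] = False

        path = sdir / f"{loc}.csv"
        _write_sensor_rows(path, t[keep], acc[:, keep], gyro[:, keep], mag[:, keep])
        sensor_paths[loc] = path.name

    # annotations on the audio clock, raw (14-label) vocabulary
    raw_intervals = []
    for s, e, cls in intervals:
        raws = _RAW_OF_CLASS[cls]
        raw = raws[rng.integers(len(raws))]
        raw_intervals.append((s - delay, e - delay, raw))
    ann_path = sdir / "annotations.tsv"
    write_annotations(AnnotationTrack(raw_intervals, source="synthetic"), ann_path)

    cg_t, cg_norms = simulate_clap_track(cfg, rng, delay, rate=60)
    cg_path = sdir / "caregiver.csv"
    _write_caregiver(cg_path, cg_t, cg_norms)

    manifest = {
        "infant_id": infant_id,
        "session_id": session_id,
        "age_point": int(age),
        "task": task,
        "sensors": {loc: name for loc, name in sensor_paths.items()},
        "annotations": ann_path.name,
        "caregiver_norms": cg_path.name,
        "clap_times_audio": [float(c) for c in cfg.clap_times_audio],
    }
    man_path = sdir / "manifest.yaml"
    write_manifest(manifest, man_path)

    truth = GroundTruth(
        session_id=session_id,
        intervals=[(float(s), float(e), c) for s, e, c in intervals],
        sync_delay=delay,
        rate=rate,
        artifact_spans=artifact_spans,
    )
    (sdir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    return man_path, truth


def _write_sensor_rows(path, t, acc, gyro, mag):
    import csv as _csv

    from .io import SENSOR_CSV_HEADER

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(SENSOR_CSV_HEADER)
        data = np.vstack([t[None, :], acc, gyro, mag]).T
        for row in data:
            w.writerow([repr(float(v)) for v in row])


def _write_caregiver(path, t, norms):
    import csv as _csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(["t", "arm_left", "arm_right"])
        for i in range(t.shape[0]):
            w.writerow([repr(float(t[i])), repr(float(norms[0, i])),
                        repr(float(norms[1, i]))])


def simulate_dataset(cfg: SimulationConfig, outdir) -> list:
    """Simulate all infants x sessions; returns manifest paths.

    Also writes ``dataset.yaml`` listing the manifests relative to outdir.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(cfg.seed)
    manifests = []
    for i in range(cfg.n_infants):
        infant_id = f"infant_{i:03d}"
        for s in range(cfg.sessions_per_infant):
            child = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(i, s))
            rng = np.random.default_rng(child)
            man, _ = simulate_session(cfg, infant_id, s, rng, outdir)
            manifests.append(man)
    write_manifest(
        {"seed": int(cfg.seed),
         "manifests": [str(m.relative_to(outdir)) for m in manifests]},
        outdir / "dataset.yaml",
    )
    del seq
    return manifests


# ---------------------------------------------------------------------------
# Benchmark presets

def _noisy_config(seed: int) -> SimulationConfig:
    base = default_orientations()
    # Hands-and-Knees pulled toward Prone, everything noisier: mimics the
    # confusion structure seen between crawling-type and prone positions
    dirs = dict(_BASE_DIR)
    dirs["Hands and Knees"] = (0.2, 0.0, -0.98)
    ori = default_orientations(dirs)
    del base
    return SimulationConfig(
        orientations=ori,
        movement_noise_sd={
            "Sitting": 0.9, "Upright": 1.1, "Supine": 0.8,
            "Prone": 0.9, "Hands and Knees": 1.4,
        },
        orientation_jitter_sd=0.12,
        seed=seed,
    )


PRESETS = {
    "separable": lambda seed: SimulationConfig(seed=seed),
    "noisy": _noisy_config,
    "ambiguous_hk": lambda seed: SimulationConfig(
        dwell_mean_s={
            "Sitting": 25.0, "Upright": 15.0, "Supine": 25.0,
            "Prone": 20.0, "Hands and Knees": 4.0,
        },
        seed=seed,
    ),
}


def make_benchmark_suite(preset: str, outdir, seed: int = 0,
                         **overrides) -> list:
    """Materialise a named preset dataset; returns its manifest paths."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[preset](seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    return simulate_dataset(cfg, Path(outdir) / preset)
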