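"""Core data model and file formats.

The package works on plain-text artefacts so that sessions are diff-able and
reproducible: one CSV per sensor location (timestamp + 9 channels), an
ELAN-export-style TSV of annotated position intervals, a YAML session manifest
tying them together, and a CSV feature-table format with a 4-line column
metadata block.

Units: acceleration in m/s^2, angular velocity in rad/s, magnetic field in
arbitrary (uncalibrated) units. Conversions are the caller's job.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LOCATIONS",
    "AGE_POINTS",
    "TASKS",
    "SENSOR_CSV_HEADER",
    "FormatError",
    "ValidationError",
    "VocabularyError",
    "SensorRecording",
    "AnnotationTrack",
    "Session",
    "FeatureTable",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_annotations",
    "write_annotations",
    "read_feature_table",
    "write_feature_table",
    "read_manifest",
    "write_manifest",
]

#: Sensor locations. The study instruments three body regions with a pair of
#: sensors each; trunk placement within the pair is not anatomically pinned,
#: so the two trunk slots are simply ``trunk_a`` / ``trunk_b``.
LOCATIONS = ("trunk_a", "trunk_b", "leg_left", "leg_right", "arm_left", "arm_right")

AGE_POINTS = (4, 6, 9, 12)
TASKS = ("book_sharing", "manipulative", "rattles")

SENSOR_CSV_HEADER = [
    "t",
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "mag_x", "mag_y", "mag_z",
]

SUPPORTED_RATES = (60, 40)


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


class VocabularyError(ValueError):
    """An annotation label is outside the position vocabulary."""


@dataclass
class SensorRecording:
    """One location's 9-channel time series.

    ``acc``/``gyro``/``mag`` are (3, T) arrays sharing the timestamp vector.
    ``artifact_mask`` marks samples excluded from analysis (True = excluded).
    """

    location: str
    timestamps: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    nominal_rate: int
    artifact_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.timestamps.shape[0], dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def duration(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def validate(self) -> None:
        t = self.timestamps
        T = t.shape[0]
        for name, arr in (("acc", self.acc), ("gyro", self.gyro), ("mag", self.mag)):
            if arr.shape != (3, T):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected (3, {T})"
                )
        if self.artifact_mask.shape != (T,):
            raise ValidationError("artifact_mask length mismatch")
        if self.nominal_rate not in SUPPORTED_RATES:
            raise ValidationError(
                f"nominal_rate must be one of {SUPPORTED_RATES}, got {self.nominal_rate}"
            )
        if T >= 2:
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                # 1-based data-row index of the first non-increasing sample
                raise ValidationError(
                    f"timestamps not strictly increasing at row {bad[0] + 2}"
                )

    def copy(self) -> "SensorRecording":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            acc=self.acc.copy(),
            gyro=self.gyro.copy(),
            mag=self.mag.copy(),
            artifact_mask=self.artifact_mask.copy(),
        )


@dataclass
class AnnotationTrack:
    """Labelled position intervals in annotation (audio/video) time.

    Gaps between intervals are transition periods and stay unlabelled.
    """

    intervals: list  # of (start_s, end_s, raw_label)
    source: str = ""

    def __post_init__(self):
        self.intervals = sorted(
            [(float(s), float(e), str(lab)) for s, e, lab in self.intervals],
            key=lambda iv: iv[0],
        )
        for s, e, lab in self.intervals:
            if not s < e:
                raise ValidationError(f"interval ({s}, {e}, {lab!r}) has start >= end")
        for (s0, e0, l0), (s1, e1, l1) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0 - 1e-12:
                raise ValidationError(
                    f"overlapping intervals: ({s0}, {e0}, {l0!r}) and ({s1}, {e1}, {l1!r})"
                )

    def shifted(self, delay_s: float) -> "AnnotationTrack":
        """Move the track onto the IMU clock (annotation time + delay)."""
        return AnnotationTrack(
            [(s + delay_s, e + delay_s, lab) for s, e, lab in self.intervals],
            source=self.source,
        )

    @property
    def duration_labelled(self) -> float:
        return float(sum(e - s for s, e, _ in self.intervals))


@dataclass
class Session:
    """One infant x age-point x task recording with its annotation track."""

    infant_id: str
    age_point: int
    task: str
    recordings: dict  # location -> SensorRecording
    annotations: AnnotationTrack
    session_id: str = ""
    sync_delay: float | None = None
    clap_times_audio: list = field(default_factory=list)
    caregiver_norm_t: np.ndarray | None = None
    caregiver_norms: np.ndarray | None = None  # (2, T): left arm, right arm

    def __post_init__(self):
        if not self.infant_id:
            raise ValidationError("infant_id must be non-empty")
        if not self.recordings:
            raise ValidationError("session needs at least one recording")
        if self.age_point not in AGE_POINTS:
            raise ValidationError(f"age_point must be one of {AGE_POINTS}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be one of {TASKS}")
        for loc in self.recordings:
            if loc not in LOCATIONS:
                raise ValidationError(f"unknown sensor location {loc!r}")
        if not self.session_id:
            self.session_id = f"{self.infant_id}_{self.age_point}m_{self.task}"


# ---------------------------------------------------------------------------
# Sensor CSV

def _infer_rate(timestamps: np.ndarray) -> int:
    """Nominal rate from median sample spacing, snapped to 60 or 40 Hz."""
    if timestamps.shape[0] < 2:
        return 60
    dt = float(np.median(np.diff(timestamps)))
    return min(SUPPORTED_RATES, key=lambda r: abs(dt - 1.0 / r))


def read_sensor_csv(path, location: str) -> SensorRecording:
    """Read one sensor location's CSV (header ``t,acc_x,...,mag_z``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise FormatError(f"cannot parse sensor CSV {path}: {exc}") from exc
    if list(df.columns) != SENSOR_CSV_HEADER:
        raise FormatError(
            f"{path}: malformed header {list(df.columns)}, expected {SENSOR_CSV_HEADER}"
        )
    t = df["t"].to_numpy(dtype=float)
    if t.shape[0] >= 2:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"{path}: timestamps not strictly increasing at row {bad[0] + 2}"
            )
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float).T
    gyro = df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float).T
    mag = df[["mag_x", "mag_y", "mag_z"]].to_numpy(dtype=float).T
    return SensorRecording(
        location=location,
        timestamps=t,
        acc=acc,
        gyro=gyro,
        mag=mag,
        nominal_rate=_infer_rate(t),
    )


def write_sensor_csv(recording: SensorRecording, path) -> None:
    path = Path(path)
    data = np.column_stack(
        [recording.timestamps, recording.acc.T, recording.gyro.T, recording.mag.T]
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SENSOR_CSV_HEADER)
        for row in data:
            w.writerow([repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# Annotation TSV

def read_annotations(path, vocabulary=None) -> AnnotationTrack:
    """Read an annotation TSV (columns start/end/label, tab-separated).

    Labels are checked against the 14-position vocabulary unless an explicit
    ``vocabulary`` iterable (or None-disabling empty set) is supplied.
    """
    from .segmentation import RAW_LABELS  # local import to avoid a cycle

    vocab = set(RAW_LABELS) if vocabulary is None else set(vocabulary)
    path = Path(path)
    intervals = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["start", "end", "label"]:
            raise FormatError(f"{path}: expected TSV header 'start\\tend\\tlabel'")
        for row in reader:
            if not row or not "".join(row).strip():
                continue
            s, e, lab = row[0], row[1], row[2]
            lab = lab.strip()
            if vocab and lab not in vocab:
                raise VocabularyError(
                    f"{path}: label {lab!r} outside the annotated-position vocabulary"
                )
            intervals.append((float(s), float(e), lab))
    return AnnotationTrack(intervals, source=str(path))


def write_annotations(track: AnnotationTrack, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["start", "end", "label"])
        for s, e, lab in track.intervals:
            w.writerow([repr(float(s)), repr(float(e)), lab])


# ---------------------------------------------------------------------------
# Feature table

#: MultiIndex level names of feature-table columns.
DESCRIPTOR_LEVELS = ("location", "signal", "group", "name")
META_COLUMNS = ("infant_id", "session_id", "window_start", "label")
FEATURE_GROUPS = ("statistical", "frequency", "summary", "difference", "correlation")


@dataclass
class FeatureTable:
    """Window x feature matrix with per-column descriptors and per-row labels.

    ``values`` is a float DataFrame whose columns are a 4-level MultiIndex
    (location, signal, group, name); ``meta`` aligns row-wise and carries
    infant_id, session_id, window_start and the 5-class label.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if list(self.meta.columns) != list(META_COLUMNS):
            raise ValidationError(f"meta columns must be {META_COLUMNS}")
        # canonical meta dtypes (pandas infers float64 for empty columns)
        self.meta = self.meta.astype(
            {"infant_id": object, "session_id": object,
             "window_start": float, "label": object}
        )
        if len(self.values) != len(self.meta):
            raise ValidationError("values and meta row counts differ")
        cols = self.values.columns
        if cols.nlevels != 4:
            raise ValidationError("feature columns need a 4-level descriptor index")
        groups = set(cols.get_level_values("group"))
        bad = groups - set(FEATURE_GROUPS)
        if bad:
            raise ValidationError(f"unknown feature groups: {sorted(bad)}")
        if cols.duplicated().any():
            raise ValidationError("duplicate feature descriptors")

    # -- modelling views ---------------------------------------------------
    @property
    def n_windows(self) -> int:
        return len(self.values)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def infant_ids(self) -> np.ndarray:
        return self.meta["infant_id"].to_numpy()

    def select_groups(self, groups, invert: bool = False) -> "FeatureTable":
        """Column subset by feature-group tag (keep-only, or drop if invert)."""
        groups = {groups} if isinstance(groups, str) else set(groups)
        tags = self.values.columns.get_level_values("group")
        keep = ~tags.isin(groups) if invert else tags.isin(groups)
        if not keep.any():
            which = "outside" if invert else "in"
            raise ValidationError(f"no feature columns {which} groups {sorted(groups)}")
        return FeatureTable(self.values.loc[:, keep], self.meta)

    def select_locations(self, locations) -> "FeatureTable":
        """Keep columns computed from the given sensor set (plus combined
        columns, which are location-tagged 'combined')."""
        locations = set(locations) | {"combined"}
        tags = self.values.columns.get_level_values("location")
        keep = tags.isin(locations)
        if not keep.any():
            raise ValidationError(f"no feature columns for locations {sorted(locations)}")
        return FeatureTable(self.values.loc[:, keep], self.meta)

    def __eq__(self, other) -> bool:  # bit-exact, for round-trip checks
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.values.columns.equals(other.values.columns)
            and np.array_equal(self.X, other.X)
            and self.meta.reset_index(drop=True).equals(other.meta.reset_index(drop=True))
        )

    @staticmethod
    def concat(tables) -> "FeatureTable":
        tables = list(tables)
        if not tables:
            raise ValidationError("nothing to concatenate")
        values = pd.concat([t.values for t in tables], ignore_index=True)
        meta = pd.concat([t.meta for t in tables], ignore_index=True)
        return FeatureTable(values, meta)


def write_feature_table(table: FeatureTable, path) -> None:
    """CSV with a 4-line column-metadata block above the data header.

    Floats are written with ``repr`` so the round trip is bit-exact.
    """
    path = Path(path)
    cols = table.values.columns
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            pad = [""] * (len(META_COLUMNS) - 1)
            for li, level in enumerate(DESCRIPTOR_LEVELS):
                w.writerow([level] + pad + [str(v) for v in cols.get_level_values(li)])
            w.writerow(list(META_COLUMNS) + [f"f{i:05d}" for i in range(len(cols))])
            vals = table.X
            meta = table.meta
            for i in range(len(meta)):
                row = [
                    str(meta.iat[i, 0]),
                    str(meta.iat[i, 1]),
                    repr(float(meta.iat[i, 2])),
                    str(meta.iat[i, 3]),
                ]
                row.extend(repr(float(v)) for v in vals[i])
                w.writerow(row)
    except OSError as exc:
        raise OSError(f"failed writing feature table to {path}: {exc}") from exc


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            levels = []
            for level in DESCRIPTOR_LEVELS:
                row = next(reader, None)
                if row is None or row[0] != level:
                    raise FormatError(f"{path}: missing {level!r} metadata line")
                levels.append(row[len(META_COLUMNS):])
            header = next(reader, None)
            if header is None or header[: len(META_COLUMNS)] != list(META_COLUMNS):
                raise FormatError(f"{path}: malformed data header")
            n_feat = len(header) - len(META_COLUMNS)
            if any(len(lv) != n_feat for lv in levels):
                raise FormatError(f"{path}: metadata/feature column count mismatch")
            meta_rows, val_rows = [], []
            for row in reader:
                if not row:
                    continue
                meta_rows.append(
                    (row[0], row[1], float(row[2]), row[3])
                )
                val_rows.append([float(v) for v in row[len(META_COLUMNS):]])
    except OSError as exc:
        raise OSError(f"failed reading feature table from {path}: {exc}") from exc
    columns = pd.MultiIndex.from_arrays(levels, names=DESCRIPTOR_LEVELS)
    values = pd.DataFrame(
        np.asarray(val_rows, dtype=float).reshape(len(val_rows), n_feat),
        columns=columns,
    )
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    meta["window_start"] = meta["window_start"].astype(float)
    for col in ("infant_id", "session_id", "label"):
        meta[col] = meta[col].astype(object)
    return FeatureTable(values, meta)


# ---------------------------------------------------------------------------
# Session manifest

def read_manifest(path) -> Session:
    """Load a YAML session manifest and everything it references."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    recordings = {}
    for loc, p in (doc.get("sensors") or {}).items():
        p = _resolve(p)
        if not p.exists():
            raise FileNotFoundError(f"manifest {path}: sensor file missing: {p}")
        recordings[loc] = read_sensor_csv(p, loc)
    ann_path = _resolve(doc["annotations"])
    if not ann_path.exists():
        raise FileNotFoundError(f"manifest {path}: annotation file missing: {ann_path}")
    annotations = read_annotations(ann_path)

    caregiver_t = caregiver_norms = None
    if doc.get("caregiver_norms"):
        cg_path = _resolve(doc["caregiver_norms"])
        if not cg_path.exists():
            raise FileNotFoundError(
                f"manifest {path}: caregiver norm file missing: {cg_path}"
            )
        cg = pd.read_csv(cg_path)
        if list(cg.columns) != ["t", "arm_left", "arm_right"]:
            raise FormatError(f"{cg_path}: expected header t,arm_left,arm_right")
        caregiver_t = cg["t"].to_numpy(dtype=float)
        caregiver_norms = cg[["arm_left", "arm_right"]].to_numpy(dtype=float).T

    return Session(
        infant_id=str(doc["infant_id"]),
        age_point=int(doc["age_point"]),
        task=str(doc["task"]),
        recordings=recordings,
        annotations=annotations,
        session_id=str(doc.get("session_id", "")),
        clap_times_audio=[float(c) for c in doc.get("clap_times_audio", [])],
        caregiver_norm_t=caregiver_t,
        caregiver_norms=caregiver_norms,
    )


def write_manifest(doc: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
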