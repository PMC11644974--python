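"""Position classes and sliding-window segmentation.

Annotators distinguish 14 body positions; dynamic positions (e.g. crawling,
walking) are folded onto their static counterparts, leaving five classes:
Sitting, Upright, Supine, Prone, Hands and Knees. Sessions are cut into 2-s
windows advanced by 1 s; a window receives a class only if at least 75% of
its samples carry that single annotation (the consistency rule) and it is not
dominated by artefact-masked samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .io import ValidationError, VocabularyError

__all__ = [
    "CLASSES",
    "RAW_LABELS",
    "CLASS_MAP",
    "UNASSIGNED",
    "map_to_static",
    "WindowSpec",
    "Window",
    "make_windows",
    "assign_window_label",
    "sample_labels",
    "label_windows",
]

#: Fixed class order used in every report.
CLASSES = ("Sitting", "Upright", "Supine", "Prone", "Hands and Knees")

UNASSIGNED = "UNASSIGNED"


def _load_class_map() -> dict:
    ref = resources.files("imuposture.data").joinpath("class_map.tsv")
    mapping = {}
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for raw, cls in reader:
            mapping[raw] = cls
    if set(mapping.values()) != set(CLASSES):
        raise ValidationError("class map is not surjective onto the 5 classes")
    return mapping


CLASS_MAP = _load_class_map()
RAW_LABELS = tuple(CLASS_MAP)


def map_to_static(raw_label: str) -> str:
    """Deterministic 14-position -> 5-class lookup."""
    try:
        return CLASS_MAP[raw_label]
    except KeyError:
        raise VocabularyError(
            f"label {raw_label!r} is not an annotated position"
        ) from None


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry and the consistency rule."""

    length_s: float = 2.0
    step_s: float = 1.0
    consistency_threshold: float = 0.75
    #: windows with more than this fraction of artefact-masked samples are
    #: left unassigned
    max_artifact_fraction: float = 0.25

    def __post_init__(self):
        if not 0 < self.step_s <= self.length_s:
            raise ValidationError("need 0 < step <= length")
        if not 0.5 < self.consistency_threshold <= 1.0:
            raise ValidationError("consistency threshold must be in (0.5, 1]")


@dataclass(frozen=True)
class Window:
    start_s: float
    end_s: float
    label: str  # one of CLASSES or UNASSIGNED
    valid_fraction: float


def make_windows(duration_s: float, spec: WindowSpec = WindowSpec()):
    """Window boundaries (start, end) covering [0, duration].

    Count is floor((duration - length) / step) + 1; below one window length
    the list is empty.
    """
    if duration_s < spec.length_s:
        return []
    n = int(np.floor((duration_s - spec.length_s) / spec.step_s + 1e-9)) + 1
    return [
        (i * spec.step_s, i * spec.step_s + spec.length_s) for i in range(n)
    ]


def assign_window_label(labels, artifact_mask=None, spec: WindowSpec = WindowSpec()):
    """Apply the consistency rule to one window's per-sample labels.

    ``labels`` holds a class name or UNASSIGNED per sample (transition samples
    are UNASSIGNED). The denominator is *all* samples in the window, so
    transition and masked samples count against the majority; masked samples
    never count toward a class. Returns (label, modal_fraction).
    """
    labels = np.asarray(labels, dtype=object)
    total = labels.shape[0]
    if total == 0:
        return UNASSIGNED, 0.0
    if artifact_mask is None:
        artifact_mask = np.zeros(total, dtype=bool)
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.mean() > spec.max_artifact_fraction:
        return UNASSIGNED, 0.0
    usable = labels[~artifact_mask]
    usable = usable[usable != UNASSIGNED]
    if usable.size == 0:
        return UNASSIGNED, 0.0
    classes, counts = np.unique(usable.astype(str), return_counts=True)
    top = counts.max()
    frac = top / total
    if frac < spec.consistency_threshold - 1e-12:
        return UNASSIGNED, float(frac)
    winners = classes[counts == top]
    if winners.size > 1:
        # modal tie: cannot reach the >50% threshold anyway, stay unassigned
        return UNASSIGNED, float(frac)
    return str(winners[0]), float(frac)


def sample_labels(grid_t, annotations, already_static: bool = False):
    """Per-sample 5-class labels on a time grid from an annotation track.

    The track must already be on the IMU clock (apply the sync delay first).
    Samples in gaps between intervals are UNASSIGNED.
    """
    grid_t = np.asarray(grid_t, dtype=float)
    out = np.full(grid_t.shape[0], UNASSIGNED, dtype=object)
    for s, e, raw in annotations.intervals:
        cls = raw if already_static else map_to_static(raw)
        lo = np.searchsorted(grid_t, s, side="left")
        hi = np.searchsorted(grid_t, e, side="left")
        out[lo:hi] = cls
    return out


def label_windows(grid_t, per_sample_labels, artifact_mask=None,
                  spec: WindowSpec = WindowSpec()):
    """Cut the grid into sliding windows and label each one.

    Returns a list of :class:`Window`. The grid is assumed uniform at the
    session's target rate, starting at its first timestamp.
    """
    grid_t = np.asarray(grid_t, dtype=float)
    if grid_t.shape[0] == 0:
        return []
    t0 = grid_t[0]
    duration = grid_t[-1] - t0
    rate = (grid_t.shape[0] - 1) / duration if duration > 0 else 0.0
    wins = make_windows(duration, spec)
    n_len = int(round(spec.length_s * rate))
    out = []
    for start, end in wins:
        lo = int(round(start * rate))
        hi = lo + n_len
        labels = per_sample_labels[lo:hi]
        mask = None if artifact_mask is None else artifact_mask[lo:hi]
        label, frac = assign_window_label(labels, mask, spec)
        out.append(Window(t0 + start, t0 + end, label, frac))
    return out
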