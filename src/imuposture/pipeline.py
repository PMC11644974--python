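"""End-to-end orchestration: manifests -> features -> CV -> reports.

Also implements the time-in-position analysis: per session and class, the
percentage of session time annotated vs predicted in that position, and the
per-class Pearson correlation of the two across sessions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .features import FeatureConfig, build_feature_matrix
from .io import FeatureTable, Session, read_manifest, write_feature_table
from .modeling import CVResults, ModelSpec, make_group_folds, train_eval
from .preprocess import PreprocessConfig, estimate_sync_delay, preprocess_recording
from .segmentation import CLASSES, UNASSIGNED, WindowSpec, label_windows, sample_labels

__all__ = [
    "RunConfig",
    "run_pipeline",
    "featurize_session",
    "featurize_manifests",
    "time_share",
]

log = logging.getLogger("imuposture")


@dataclass(frozen=True)
class RunConfig:
    preprocess: PreprocessConfig = PreprocessConfig()
    window: WindowSpec = WindowSpec()
    features: FeatureConfig = FeatureConfig()
    model: ModelSpec = ModelSpec()
    k_folds: int = 5
    seed: int = 0

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        def _plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [_plain(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): _plain(v) for k, v in obj.items()}
            return obj
        return _plain(self)


def featurize_session(session: Session, config: RunConfig):
    """Preprocess, synchronise, window and featurise one session.

    Returns (FeatureTable, windows, duration_s, sync_delay).
    """
    fcfg = config.features
    derived = {}
    for loc in fcfg.sensor_set:
        if loc not in session.recordings:
            raise KeyError(
                f"session {session.session_id}: sensor {loc} required by the "
                "feature config but absent"
            )
        derived[loc] = preprocess_recording(session.recordings[loc], config.preprocess)

    if session.caregiver_norms is not None and session.clap_times_audio:
        delay = estimate_sync_delay(
            session.caregiver_norms, session.caregiver_norm_t,
            session.clap_times_audio, config.preprocess,
        )
    else:
        delay = 0.0
    annotations = session.annotations.shifted(delay)

    n = min(d.timestamps.shape[0] for d in derived.values())
    grid = next(iter(derived.values())).timestamps[:n]
    mask = np.zeros(n, dtype=bool)
    for d in derived.values():
        mask |= d.artifact_mask[:n]
        d.timestamps = d.timestamps[:n]
        d.channels = {k: v[:n] for k, v in d.channels.items()}
        d.artifact_mask = d.artifact_mask[:n]

    labels = sample_labels(grid, annotations)
    windows = label_windows(grid, labels, mask, config.window)
    table = build_feature_matrix(
        derived, windows, fcfg,
        infant_id=session.infant_id, session_id=session.session_id,
        rate=config.preprocess.target_rate, length_s=config.window.length_s,
    )
    duration = float(grid[-1] - grid[0]) if n else 0.0
    return table, windows, duration, delay


def featurize_manifests(manifests, config: RunConfig):
    """Featurise many sessions; returns (FeatureTable, windows_by_session,
    durations_by_session)."""
    tables, windows_by, durations = [], {}, {}
    for man in manifests:
        session = read_manifest(man)
        table, windows, duration, _ = featurize_session(session, config)
        tables.append(table)
        windows_by[session.session_id] = windows
        durations[session.session_id] = duration
    return FeatureTable.concat(tables), windows_by, durations


# ---------------------------------------------------------------------------
# Time-in-position shares

def _window_contributions(windows, step_s: float, length_s: float):
    """Seconds each labelled window contributes to temporal sums.

    Overlapping windows count their step only; the session's final window
    counts its full length, so a fully labelled session sums to its duration
    without double-counting overlap.
    """
    if not windows:
        return {}
    last_start = max(w.start_s for w in windows)
    return {
        w.start_s: (length_s if w.start_s == last_start else step_s)
        for w in windows if w.label != UNASSIGNED
    }


def time_share(windows_by_session: dict, predictions: pd.DataFrame,
               durations: dict, step_s: float = 1.0, length_s: float = 2.0):
    """Annotated and predicted time-in-position percentages per session.

    ``predictions`` needs columns session_id, window_start, pred (held-out CV
    predictions). Returns (tidy per-session DataFrame, per-class Pearson-r
    DataFrame). Sessions with zero duration are skipped with a warning.
    """
    import warnings

    pred_lookup = {
        (r.session_id, round(float(r.window_start), 6)): r.pred
        for r in predictions.itertuples()
    }
    rows = []
    for sid, windows in windows_by_session.items():
        duration = durations.get(sid, 0.0)
        if duration <= 0:
            warnings.warn(f"session {sid} has zero duration; skipped", UserWarning,
                          stacklevel=2)
            continue
        contrib = _window_contributions(windows, step_s, length_s)
        ann = dict.fromkeys(CLASSES, 0.0)
        pred = dict.fromkeys(CLASSES, 0.0)
        for w in windows:
            if w.label == UNASSIGNED:
                continue
            c = contrib[w.start_s]
            ann[w.label] += c
            p = pred_lookup.get((sid, round(float(w.start_s), 6)))
            if p is not None and p in pred:
                pred[p] += c
        for cls in CLASSES:
            rows.append({
                "session_id": sid, "class": cls,
                "annotated_pct": 100.0 * ann[cls] / duration,
                "predicted_pct": 100.0 * pred[cls] / duration,
            })
    tidy = pd.DataFrame(
        rows, columns=["session_id", "class", "annotated_pct", "predicted_pct"]
    )
    corr_rows = []
    for cls in CLASSES:
        sub = tidy[tidy["class"] == cls]
        a = sub["annotated_pct"].to_numpy()
        p = sub["predicted_pct"].to_numpy()
        if len(sub) >= 2 and a.std() > 0 and p.std() > 0:
            r, _ = stats.pearsonr(a, p)
        else:
            r = np.nan
        corr_rows.append({"class": cls, "pearson_r": r, "n_sessions": len(sub)})
    return tidy, pd.DataFrame(corr_rows)


# ---------------------------------------------------------------------------

def run_pipeline(manifests, config: RunConfig, outdir) -> Path:
    """preprocess -> sync -> segmentation -> features -> CV -> reports.

    Everything is seeded from ``config``; rerunning with the same inputs and
    seed reproduces all CSV outputs bit-exactly. On failure, partial outputs
    are retained under ``<outdir>/failed/``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    session_id = "-"
    try:
        with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({"seed": config.seed, "config": config.to_dict()}, fh)

        stage = "featurize"
        tables, windows_by, durations = [], {}, {}
        for man in manifests:
            session = read_manifest(man)
            session_id = session.session_id
            table, windows, duration, delay = featurize_session(session, config)
            log.info("session %s: %d labelled windows, delay %.4f s",
                     session_id, table.n_windows, delay)
            tables.append(table)
            windows_by[session_id] = windows
            durations[session_id] = duration
        session_id = "-"
        table = FeatureTable.concat(tables)
        write_feature_table(table, outdir / "features.csv")

        stage = "modeling"
        folds = make_group_folds(table.infant_ids, k=config.k_folds,
                                 seed=config.seed)
        results = train_eval(table, config.model, folds)
        _write_model_reports(results, outdir)

        stage = "time_share"
        tidy, corr = time_share(
            windows_by, results.predictions, durations,
            step_s=config.window.step_s, length_s=config.window.length_s,
        )
        tidy.to_csv(outdir / "timeshare.csv", index=False)
        corr.to_csv(outdir / "timeshare_correlation.csv", index=False)
        log.info("done")
        return outdir
    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "error.txt").write_text(
            f"stage: {stage}\nsession: {session_id}\nerror: {exc}\n",
            encoding="utf-8",
        )
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (session {session_id}): {exc}"
        ) from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_model_reports(results: CVResults, outdir: Path) -> None:
    results.f1_matrix().to_csv(outdir / "fold_f1.csv")
    results.summary().to_csv(outdir / "f1_summary.csv")
    preds = results.predictions
    preds.to_csv(outdir / "predictions.csv", index=False)
    conf = results.confusion_summary()
    frames = []
    for key in ("percent", "count_mean", "count_se"):
        df = pd.DataFrame(conf[key], index=list(results.classes),
                          columns=list(results.classes))
        df.insert(0, "metric", key)
        frames.append(df)
    pd.concat(frames).to_csv(outdir / "confusion.csv")
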