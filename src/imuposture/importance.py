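"""Feature-group and sensor-set importance.

Three complementary views: ablation (retrain with one feature group kept or
dropped, report the per-class percentage change in F1 against the all-groups
reference on identical folds); |SHAP| aggregation (exact TreeSHAP
attributions of the gradient-boosted model, absolute values summed over the
five class outputs, then summed/averaged within each signal x group cell);
and sensor-subset comparison (Trunk vs Trunk+Legs vs Trunk+Legs+Arms) with a
Friedman test across folds and Benjamini-Hochberg adjustment across the five
position classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, ValidationError
from .modeling import CVResults, ModelSpec, train_eval
from .segmentation import CLASSES

__all__ = [
    "SENSOR_SETS",
    "AblationReport",
    "ShapGroupReport",
    "SensorSetComparison",
    "ablate",
    "shap_values_per_feature",
    "shap_group_importance",
    "shap_group_report_cv",
    "friedman_from_scores",
    "compare_sensor_sets",
]

#: The three nested sensor subsets compared in the study.
SENSOR_SETS = {
    "Trunk": ("trunk_a", "trunk_b"),
    "Trunk+Legs": ("trunk_a", "trunk_b", "leg_left", "leg_right"),
    "Trunk+Legs+Arms": (
        "trunk_a", "trunk_b", "leg_left", "leg_right", "arm_left", "arm_right"
    ),
}


# ---------------------------------------------------------------------------
# Ablation

@dataclass
class AblationReport:
    mode: str                     # "only_group" | "without_group"
    group: str
    delta_f1_pct: pd.DataFrame    # folds x classes, percent change
    reference: CVResults
    ablated: CVResults

    def mean_delta(self) -> pd.Series:
        return self.delta_f1_pct.mean(axis=0, skipna=True)


def ablate(table: FeatureTable, spec: ModelSpec, folds: dict,
           mode: str, group: str, reference: CVResults | None = None) -> AblationReport:
    """Retrain with a feature group kept alone or removed.

    Fold assignment and seed are identical to the reference run, so the F1
    differences are paired. ``delta = 100 * (F1_ablated - F1_all) / F1_all``
    per class and fold.
    """
    if mode not in ("only_group", "without_group"):
        raise ValidationError("mode must be only_group|without_group")
    if reference is None:
        reference = train_eval(table, spec, folds)
    tags = set(table.values.columns.get_level_values("group"))
    if mode == "without_group" and group not in tags:
        # nothing to remove: the model is unchanged by construction
        sub = table
    else:
        sub = table.select_groups(group, invert=(mode == "without_group"))
    ablated = train_eval(sub, spec, folds)
    ref = reference.f1_matrix()
    abl = ablated.f1_matrix()
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * (abl - ref) / ref
    delta = delta.where(ref != 0)
    return AblationReport(mode, group, delta, reference, ablated)


# ---------------------------------------------------------------------------
# |SHAP| aggregation

def shap_values_per_feature(model, X: np.ndarray) -> np.ndarray:
    """Per-row, per-feature |SHAP|, summed over the class outputs.

    Uses the model's native exact TreeSHAP path (LightGBM ``pred_contrib``,
    XGBoost ``pred_contribs``). Returns an (n_rows, n_features) array.
    """
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    booster = getattr(model, "booster_", model)
    if hasattr(booster, "predict") and type(booster).__module__.startswith("lightgbm"):
        contrib = booster.predict(X, pred_contrib=True)
        contrib = np.asarray(contrib).reshape(n, -1, f + 1)[:, :, :f]
        return np.abs(contrib).sum(axis=1)
    if type(model).__module__.startswith("xgboost"):
        import xgboost as xgb

        bst = model.get_booster() if hasattr(model, "get_booster") else model
        contrib = bst.predict(xgb.DMatrix(X), pred_contribs=True)
        contrib = np.asarray(contrib)
        if contrib.ndim == 2:  # binary: (n, f+1)
            contrib = contrib[:, None, :]
        return np.abs(contrib[:, :, :f]).sum(axis=1)
    raise TypeError(
        "model must be a tree ensemble with native additive Shapley "
        f"attribution (LightGBM or XGBoost), got {type(model).__name__}"
    )


@dataclass
class ShapGroupReport:
    """|SHAP| totals partitioned into (signal, group) cells.

    ``table`` has columns signal, group, sum, mean, n_features; the cell sums
    partition the total per-feature |SHAP| sum exactly, and mean equals
    sum / n_features.
    """

    table: pd.DataFrame
    per_feature: pd.Series  # indexed by full descriptor

    @property
    def total(self) -> float:
        return float(self.per_feature.sum())


def shap_group_importance(model, X, descriptors) -> ShapGroupReport:
    """Aggregate per-feature mean |SHAP| into (signal, group) cells.

    ``descriptors`` is the 4-level column MultiIndex of the features that
    ``model`` was fitted on, in fit order.
    """
    X = np.asarray(X, dtype=float)
    if len(descriptors) != X.shape[1]:
        orphans = abs(len(descriptors) - X.shape[1])
        raise ValidationError(
            f"descriptor/feature mismatch: {len(descriptors)} descriptors vs "
            f"{X.shape[1]} model features ({orphans} orphans)"
        )
    per_row = shap_values_per_feature(model, X)
    per_feature = pd.Series(per_row.mean(axis=0), index=descriptors)
    cells = pd.DataFrame(
        {
            "signal": descriptors.get_level_values("signal"),
            "group": descriptors.get_level_values("group"),
            "shap": per_feature.to_numpy(),
        }
    )
    grouped = cells.groupby(["signal", "group"], sort=True)["shap"]
    sums = grouped.sum()
    counts = grouped.size()
    table = pd.DataFrame(
        {
            "sum": sums,
            "mean": sums / counts,  # exactly sum/count by construction
            "n_features": counts,
        }
    ).reset_index()
    return ShapGroupReport(table=table, per_feature=per_feature)


def shap_group_report_cv(results: CVResults, table: FeatureTable,
                         rows: str = "test") -> pd.DataFrame:
    """(signal, group) |SHAP| sums and means with across-fold mean +/- SE.

    Attributions are computed on each fold's held-out rows by default,
    matching the cross-validation framing (set ``rows='train'`` to flip).
    """
    X = table.X
    fold_frames = []
    for f in results.folds:
        test_rows = f.predictions["row"].to_numpy()
        if rows == "train":
            sel = np.setdiff1d(np.arange(len(table.values)), test_rows)
        else:
            sel = test_rows
        rep = shap_group_importance(f.model, X[sel], table.values.columns)
        df = rep.table.set_index(["signal", "group"])[["sum", "mean"]]
        fold_frames.append(df)
    stacked = pd.concat(fold_frames, keys=range(len(fold_frames)), names=["fold"])
    agg = stacked.groupby(level=["signal", "group"]).agg(["mean", "sem"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()


# ---------------------------------------------------------------------------
# Sensor-set comparison

def friedman_from_scores(scores: np.ndarray):
    """Friedman chi-square over a blocks x treatments score matrix."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < 3 or scores.shape[1] < 3:
        raise ValidationError("Friedman test needs >=3 blocks and >=3 treatments")
    if np.all(scores.max(axis=1) == scores.min(axis=1)):
        # every block fully tied: no evidence of any treatment difference
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*[scores[:, j] for j in range(scores.shape[1])])
    return float(stat), float(p)


@dataclass
class SensorSetComparison:
    f1: pd.DataFrame          # columns: set, class, fold, f1 (tidy)
    tests: pd.DataFrame       # per class: statistic, p, p_fdr, reject
    results: dict             # set name -> CVResults


def compare_sensor_sets(tables: dict, spec: ModelSpec, folds: dict,
                        alpha: float = 0.05) -> SensorSetComparison:
    """Paired comparison of sensor subsets on identical folds.

    ``tables`` maps set name -> FeatureTable (same windows, different column
    subsets — build them with :meth:`FeatureTable.select_locations` or by
    re-extracting with each sensor set). Per class, a Friedman test ranks the
    sets within each fold; p-values are Benjamini-Hochberg adjusted across
    the family of five classes. Classes with fewer than 3 complete fold
    blocks are skipped with a warning entry (NaN p).
    """
    import warnings as _warnings

    set_names = list(tables)
    results = {name: train_eval(tables[name], spec, folds) for name in set_names}
    tidy = []
    for name, res in results.items():
        m = res.f1_matrix()
        for fold, row in m.iterrows():
            for cls in CLASSES:
                tidy.append({"set": name, "class": cls, "fold": fold, "f1": row[cls]})
    tidy = pd.DataFrame(tidy)

    rows = []
    for cls in CLASSES:
        wide = tidy[tidy["class"] == cls].pivot(index="fold", columns="set", values="f1")
        wide = wide[set_names].dropna()
        if len(wide) < 3 or len(set_names) < 3:
            _warnings.warn(
                f"class {cls}: fewer than 3 paired fold blocks; Friedman test skipped",
                UserWarning,
                stacklevel=2,
            )
            rows.append({"class": cls, "statistic": np.nan, "p": np.nan})
            continue
        stat, p = friedman_from_scores(wide.to_numpy())
        rows.append({"class": cls, "statistic": stat, "p": p})
    tests = pd.DataFrame(rows)
    mask = tests["p"].notna()
    p_fdr = np.full(len(tests), np.nan)
    reject = np.zeros(len(tests), dtype=bool)
    if mask.any():
        rej, adj, _, _ = multipletests(tests.loc[mask, "p"], alpha=alpha, method="fdr_bh")
        p_fdr[mask.to_numpy()] = adj
        reject[mask.to_numpy()] = rej
    tests["p_fdr"] = p_fdr
    tests["reject"] = reject
    return SensorSetComparison(f1=tidy, tests=tests, results=results)
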