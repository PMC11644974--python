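"""Classifier training under infant-grouped 5-fold cross-validation.

Two tree-ensemble families are supported: a random forest (scikit-learn,
n_estimators=1000, max_depth=6, class_weight='balanced') and a gradient-
boosted model (LightGBM). Folds are built over infants, never windows, so
all recordings of an infant sit in exactly one test fold — the leakage
guard. :class:`PositionClassifier` is the model object; its :meth:`fit`
returns :class:`CVResults` carrying per-fold per-class F1 scores, held-out
predictions, confusion counts and the fitted fold models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score

from .io import FeatureTable, ValidationError
from .segmentation import CLASSES

__all__ = [
    "ModelSpec",
    "FoldResult",
    "CVResults",
    "PositionClassifier",
    "make_group_folds",
    "train_eval",
]

_RF_DEFAULTS = {
    "n_estimators": 1000,
    "max_depth": 6,
    "class_weight": "balanced",
}

# Gradient-boosted defaults chosen for single-core tractability at full
# dataset scale (see docs/methods.md); everything is overridable.
_GBT_DEFAULTS = {
    "n_estimators": 200,
    "max_depth": 6,
    "learning_rate": 0.1,
    "num_leaves": 63,
    "class_weight": "balanced",
    "feature_fraction": 0.5,
    "max_bin": 63,
}

FAMILIES = ("random_forest", "gradient_boosted_trees")


@dataclass(frozen=True)
class ModelSpec:
    family: str = "gradient_boosted_trees"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}")

    def resolved_hyperparameters(self) -> dict:
        base = dict(_RF_DEFAULTS if self.family == "random_forest" else _GBT_DEFAULTS)
        base.update(self.hyperparameters)
        return base

    def make_estimator(self):
        hp = self.resolved_hyperparameters()
        if self.family == "random_forest":
            return RandomForestClassifier(
                random_state=self.seed, n_jobs=1, **hp
            )
        import lightgbm as lgb

        return lgb.LGBMClassifier(
            random_state=self.seed,
            n_jobs=1,
            verbose=-1,
            deterministic=True,
            force_col_wise=True,
            **hp,
        )


def make_group_folds(infant_ids, k: int = 5, seed: int = 0) -> dict:
    """Deal shuffled infants round-robin into k folds.

    Returns infant_id -> fold index; the assignment depends only on the set
    of infant ids and the seed, never on row order.
    """
    infants = sorted(set(map(str, infant_ids)))
    if len(infants) < k:
        raise ValidationError(f"need at least {k} infants, got {len(infants)}")
    order = np.random.default_rng(seed).permutation(len(infants))
    return {infants[j]: i % k for i, j in enumerate(order)}


@dataclass
class FoldResult:
    fold: int
    test_infants: tuple
    f1_per_class: dict          # class -> F1 or NaN (class absent from train)
    predictions: pd.DataFrame   # row_index, true, pred
    confusion: np.ndarray       # 5x5 counts, rows = true class
    model: object = None


class CVResults:
    """Cross-validated estimates with per-fold detail.

    ``summary()`` gives the headline table: per-class mean F1 across folds
    with its standard error (sd over folds / sqrt(n folds)).
    """

    def __init__(self, folds, classes=CLASSES, spec: ModelSpec | None = None,
                 fold_of_infant: dict | None = None):
        if not folds:
            raise ValidationError("CVResults needs at least one fold")
        self.folds = list(folds)
        self.classes = tuple(classes)
        self.spec = spec
        self.fold_of_infant = dict(fold_of_infant or {})

    @property
    def k(self) -> int:
        return len(self.folds)

    def f1_matrix(self) -> pd.DataFrame:
        """folds x classes matrix of F1 scores (NaN where undefined)."""
        return pd.DataFrame(
            [[f.f1_per_class.get(c, np.nan) for c in self.classes] for f in self.folds],
            columns=list(self.classes),
            index=[f.fold for f in self.folds],
        )

    def summary(self) -> pd.DataFrame:
        m = self.f1_matrix()
        n = m.notna().sum(axis=0)
        mean = m.mean(axis=0, skipna=True)
        se = m.std(axis=0, ddof=1, skipna=True) / np.sqrt(n.clip(lower=1))
        out = pd.DataFrame({"mean_f1": mean, "se_f1": se, "n_folds": n})
        out.index.name = "class"
        return out

    def macro_f1(self) -> float:
        return float(self.summary()["mean_f1"].mean())

    @property
    def predictions(self) -> pd.DataFrame:
        """All held-out predictions, one row per window."""
        frames = []
        for f in self.folds:
            df = f.predictions.copy()
            df["fold"] = f.fold
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def confusion_summary(self):
        """Per-cell mean count, SE over folds, and row percentages.

        Percentages are row-normalised from the mean counts, so each true
        class row sums to 100 (up to rounding); true classes never observed
        in any test fold are flagged undefined (NaN row).
        """
        counts = np.stack([f.confusion for f in self.folds])  # (k, 5, 5)
        mean = counts.mean(axis=0)
        se = counts.std(axis=0, ddof=1) / np.sqrt(self.k) if self.k > 1 else np.zeros_like(mean)
        row_tot = mean.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row_tot > 0, 100.0 * mean / np.where(row_tot > 0, row_tot, 1.0), np.nan)
        undefined = [c for c, tot in zip(self.classes, row_tot[:, 0]) if tot == 0]
        if undefined:
            warnings.warn(
                f"true classes with no test windows in any fold: {undefined}",
                UserWarning,
                stacklevel=2,
            )
        return {"percent": pct, "count_mean": mean, "count_se": se,
                "classes": self.classes, "undefined_rows": undefined}


class PositionClassifier:
    """Position-classification model over a feature table.

    Parameters
    ----------
    table : FeatureTable
        Window x feature matrix with labels and infant ids.
    spec : ModelSpec
        Classifier family, hyperparameters and seed.
    """

    def __init__(self, table: FeatureTable, spec: ModelSpec = ModelSpec()):
        if len(set(table.y)) < 2:
            raise ValidationError("need at least 2 classes to fit")
        self.table = table
        self.spec = spec

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, meta: pd.DataFrame,
                       spec: ModelSpec = ModelSpec()) -> "PositionClassifier":
        return cls(FeatureTable(values, meta), spec)

    def fit(self, folds: dict | None = None, k: int = 5) -> CVResults:
        """Run infant-grouped k-fold CV; returns :class:`CVResults`.

        ``folds`` may carry a precomputed infant -> fold map (reused across
        ablations and sensor-set comparisons so runs stay paired).
        """
        table = self.table
        if folds is None:
            folds = make_group_folds(table.infant_ids, k=k, seed=self.spec.seed)
        X = table.X
        y = table.y.astype(str)
        fold_of_row = np.array([folds[str(i)] for i in table.infant_ids])
        k_actual = max(folds.values()) + 1
        results = []
        for f in range(k_actual):
            test = fold_of_row == f
            train = ~test
            if not test.any():
                continue
            est = self.spec.make_estimator()
            present = set(y[train])
            absent = [c for c in CLASSES if c not in present]
            if absent:
                warnings.warn(
                    f"fold {f}: classes absent from training split: {absent}; "
                    "their fold F1 is recorded as missing",
                    UserWarning,
                    stacklevel=2,
                )
            est.fit(X[train], y[train])
            pred = np.asarray(est.predict(X[test]), dtype=object).astype(str)
            f1 = f1_score(
                y[test], pred, labels=list(CLASSES), average=None, zero_division=0
            )
            true_counts = {c: int((y[test] == c).sum()) for c in CLASSES}
            pred_counts = {c: int((pred == c).sum()) for c in CLASSES}
            f1_per_class = {}
            for c, v in zip(CLASSES, f1):
                if c in absent or (true_counts[c] == 0 and pred_counts[c] == 0):
                    # F1 undefined: class unseen in training, or no true and
                    # no predicted windows in this test fold (P + R = 0/0)
                    f1_per_class[c] = np.nan
                else:
                    f1_per_class[c] = float(v)
            conf = confusion_matrix(y[test], pred, labels=list(CLASSES))
            preds = pd.DataFrame(
                {
                    "row": np.nonzero(test)[0],
                    "infant_id": table.infant_ids[test],
                    "session_id": table.meta["session_id"].to_numpy()[test],
                    "window_start": table.meta["window_start"].to_numpy()[test],
                    "true": y[test],
                    "pred": pred,
                }
            )
            results.append(
                FoldResult(
                    fold=f,
                    test_infants=tuple(sorted(set(map(str, table.infant_ids[test])))),
                    f1_per_class=f1_per_class,
                    predictions=preds,
                    confusion=conf,
                    model=est,
                )
            )
        return CVResults(results, CLASSES, self.spec, folds)


def train_eval(table: FeatureTable, spec: ModelSpec = ModelSpec(),
               folds: dict | None = None, k: int = 5) -> CVResults:
    """Functional wrapper around :class:`PositionClassifier`."""
    return PositionClassifier(table, spec).fit(folds=folds, k=k)
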