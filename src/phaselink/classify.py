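"""Subject-level classification with random forests, RFE and LOOCV.

The classifier separates patients from controls using any combination of
three feature sets: regional/global connectivity, graph + tree topology
metrics, and the MMSE cognitive score.  Feature selection is recursive
feature elimination driven by forest importances, refit inside every
leave-one-out fold (no leakage), and the pooled held-out predictions form a
single confusion matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE

__all__ = [
    "FeatureTable",
    "ConfusionMatrix",
    "ClassificationReport",
    "build_feature_table",
    "confusion_metrics",
    "rfe_rf_loocv",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Subjects x named features, with group labels and per-column provenance."""

    X: pd.DataFrame
    y: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        if self.X.columns.duplicated().any():
            dupes = self.X.columns[self.X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dupes}")
        if self.X.isna().any().any():
            bad = self.X.index[self.X.isna().any(axis=1)].tolist()
            raise ValueError(f"missing feature values for subjects: {bad}")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ClassificationReport:
    confusion: ConfusionMatrix
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    selected_features: list[tuple[str, int]]  # (feature, folds in which selected)
    fold_predictions: pd.DataFrame  # subject, truth, prediction

    def to_json(self, path) -> None:
        payload = {
            "confusion": vars(self.confusion),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "selected_features": self.selected_features,
            "fold_predictions": self.fold_predictions.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_feature_table(
    tables: Mapping[str, pd.DataFrame | pd.Series],
    labels: pd.Series,
    feature_sets: Sequence[str],
) -> FeatureTable:
    """Assemble a feature table from named per-subject blocks.

    ``tables`` maps a set name (e.g. ``"connectivity"``, ``"topology"``,
    ``"mmse"``) to a subject-indexed DataFrame (or Series); ``feature_sets``
    picks which blocks enter.  A subject missing any requested feature is an
    assembly error naming the subject.
    """
    unknown = [s for s in feature_sets if s not in tables]
    if unknown:
        raise KeyError(f"unknown feature set(s) {unknown}; have {sorted(tables)}")
    if not feature_sets:
        raise ValueError("at least one feature set required")
    blocks = []
    provenance: dict[str, str] = {}
    for name in feature_sets:
        block = tables[name]
        if isinstance(block, pd.Series):
            block = block.to_frame(name)
        block = block.reindex(labels.index)
        if block.isna().any().any():
            missing = block.index[block.isna().any(axis=1)].tolist()
            raise ValueError(f"subjects missing {name!r} features: {missing}")
        for col in block.columns:
            if col in provenance:
                raise ValueError(f"duplicate feature column {col!r}")
            provenance[col] = name
        blocks.append(block)
    X = pd.concat(blocks, axis=1)
    return FeatureTable(X, labels, provenance)


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, sensitivity and F1 from a confusion matrix.

    Undefined ratios (no predicted or no actual positives) are returned as
    NaN with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp == 0:
        warnings.warn("no predicted positives: precision undefined", stacklevel=2)
        precision = float("nan")
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        warnings.warn("no actual positives: sensitivity undefined", stacklevel=2)
        sensitivity = float("nan")
    else:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "f1": f1,
    }


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 1000003 + fold * 7919 + 1) % (2**31 - 1))


def _fit_rfe(
    X: np.ndarray,
    y: np.ndarray,
    n_select: int,
    n_trees: int,
    step: float,
    seed: int,
) -> np.ndarray:
    """Boolean mask of features kept by importance-driven RFE."""
    if n_select >= X.shape[1]:
        return np.ones(X.shape[1], dtype=bool)
    rfe = RFE(
        RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1),
        n_features_to_select=n_select,
        step=step,
    )
    rfe.fit(X, y)
    return rfe.support_


def rfe_rf_loocv(
    table: FeatureTable,
    seed: int = 0,
    n_trees: int = 200,
    n_select: int | str = 20,
    rfe_step: float = 0.2,
    positive_class: str = "aMCI",
) -> ClassificationReport:
    """Leave-one-out evaluation of a random forest with per-fold RFE.

    In every fold, RFE (step = ``rfe_step`` as a fraction of the feature
    count) is fitted on the training subjects only; a fresh seeded forest is
    then trained on the selected features and predicts the held-out subject.
    ``n_select="auto"`` picks the feature count from {5, 10, 20, 40} by
    out-of-bag score on the training data.  Pooled predictions form one
    confusion matrix; folds whose training set loses a class are skipped
    with a warning.
    """
    X = table.X.to_numpy(dtype=float)
    y = (table.y == positive_class).to_numpy()
    classes = np.unique(y)
    if classes.size != 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 subjects in each class")
    n = len(y)
    preds = np.zeros(n, dtype=bool)
    skipped: list[int] = []
    select_counts = np.zeros(table.n_features, dtype=int)
    for fold in range(n):
        train = np.ones(n, dtype=bool)
        train[fold] = False
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {fold}: a class has a single subject; skipped", stacklevel=2)
            skipped.append(fold)
            continue
        fs = _fold_seed(seed, fold)
        k = n_select
        if k == "auto":
            k = _auto_n_select(X[train], y[train], n_trees, rfe_step, fs)
        mask = _fit_rfe(X[train], y[train], int(k), n_trees, rfe_step, fs)
        select_counts += mask
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=fs + 1, n_jobs=1)
        clf.fit(X[train][:, mask], y[train])
        preds[fold] = clf.predict(X[fold : fold + 1, mask])[0]
    kept = np.array([i for i in range(n) if i not in skipped])
    t, p = y[kept], preds[kept]
    cm = ConfusionMatrix(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )
    metrics = confusion_metrics(cm)
    ranked = sorted(
        zip(table.X.columns, select_counts), key=lambda kv: (-kv[1], kv[0])
    )
    fold_df = pd.DataFrame(
        {
            "subject": table.X.index[kept],
            "truth": np.where(t, positive_class, "other"),
            "prediction": np.where(p, positive_class, "other"),
        }
    )
    return ClassificationReport(
        confusion=cm,
        accuracy=metrics["accuracy"],
        precision=metrics["precision"],
        sensitivity=metrics["sensitivity"],
        f1=metrics["f1"],
        selected_features=[(f, int(c)) for f, c in ranked if c > 0],
        fold_predictions=fold_df,
    )


def _auto_n_select(
    X: np.ndarray, y: np.ndarray, n_trees: int, step: float, seed: int
) -> int:
    """Pick the RFE target from a small grid by out-of-bag score."""
    best_k, best_score = X.shape[1], -np.inf
    for k in (5, 10, 20, 40):
        if k > X.shape[1]:
            continue
        mask = _fit_rfe(X, y, k, n_trees, step, seed)
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + 2, oob_score=True,
            bootstrap=True, n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[:, mask], y)
        score = getattr(clf, "oob_score_", -np.inf)
        if score > best_score:
            best_k, best_score = k, score
    return best_k
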