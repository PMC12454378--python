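"""Stratified 5-fold cross-validation, confusion-matrix metrics and ROC.

Per fold, four fifths of the samples train a head (the MLP additionally
holds out an inner 80:20 validation split for early stopping) and the
remaining fifth is tested, so every sample is tested exactly once.  Metrics
follow the one-vs-rest reduction: per class c, TP = cm[c,c], FN/FP are the
off-diagonal row/column sums and TN the remainder, from which

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    recall      = TP / (TP + FN)
    precision   = TP / (TP + FP)
    f1          = 2·TP / (2·TP + FP + FN)
    specificity = TN / (TN + FP)

are macro-averaged.  Multiclass accuracy is trace/total.  A zero denominator
yields 0 and raises a flag (never NaN).  Headline numbers are reported both
as the unweighted mean over folds (the default) and pooled over the summed
confusion matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_curve as sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .phantoms import CLASSES

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "EvalReport",
    "make_folds",
    "confusion",
    "metrics_from_confusion",
    "roc_one_vs_rest",
    "cross_validate",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "specificity")


@dataclass
class FoldAssignment:
    fold_of: np.ndarray  # per-sample fold index 0..n_folds-1
    n_folds: int
    seed: int
    stratified: bool = True

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass
class ConfusionMatrix:
    """rows = actual class, cols = predicted class, in ``class_order``."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.class_order)
        if self.counts.shape != (n, n):
            raise ValueError(f"confusion matrix must be {n}x{n}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    accuracy: float  # multiclass trace/total
    zero_denominator_flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro": self.macro,
            "per_class": self.per_class,
            "zero_denominator_flags": self.zero_denominator_flags,
        }


@dataclass
class RocCurve:
    class_label: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    defined: bool = True


@dataclass
class EvalReport:
    """Everything the 5-fold protocol produces for one classifier head."""

    fold_confusions: list[ConfusionMatrix]
    fold_metrics: list[MetricsReport]
    mean_metrics: dict[str, float]  # unweighted mean over folds
    pooled: MetricsReport  # from the summed confusion matrix
    roc: list[RocCurve]
    macro_auc: float

    def as_dict(self) -> dict:
        return {
            "mean_over_folds": self.mean_metrics,
            "pooled": self.pooled.as_dict(),
            "per_fold": [m.as_dict() for m in self.fold_metrics],
            "fold_confusions": [c.counts.tolist() for c in self.fold_confusions],
            "macro_auc": self.macro_auc,
            "auc_per_class": {r.class_label: r.auc for r in self.roc if r.defined},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)


def make_folds(
    labels: Sequence[str], n_folds: int = 5, seed: int = 0
) -> FoldAssignment:
    """Stratified partition into ``n_folds`` test folds, seeded."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"every class needs >= {n_folds} members for {n_folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = fold
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds, seed=seed)


def confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_order: tuple[str, ...] = CLASSES,
) -> ConfusionMatrix:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    known = set(class_order)
    bad = (set(y_true) | set(y_pred)) - known
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected {class_order}")
    counts = sk_confusion(y_true, y_pred, labels=list(class_order))
    return ConfusionMatrix(counts=counts, class_order=class_order)


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest per-class metrics and their macro averages."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    for i, label in enumerate(cm.class_order):
        tp = float(cm.counts[i, i])
        fn = float(cm.counts[i, :].sum() - tp)
        fp = float(cm.counts[:, i].sum() - tp)
        tn = float(total - tp - fn - fp)
        per_class[label] = {
            "accuracy": _safe_div(tp + tn, tp + tn + fp + fn, flags, f"{label}.accuracy"),
            "precision": _safe_div(tp, tp + fp, flags, f"{label}.precision"),
            "recall": _safe_div(tp, tp + fn, flags, f"{label}.recall"),
            "f1": _safe_div(2 * tp, 2 * tp + fp + fn, flags, f"{label}.f1"),
            "specificity": _safe_div(tn, tn + fp, flags, f"{label}.specificity"),
        }
    macro = {
        m: float(np.mean([per_class[c][m] for c in cm.class_order]))
        for m in METRIC_NAMES
    }
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        accuracy=float(np.trace(cm.counts) / total),
        zero_denominator_flags=flags,
    )


def roc_one_vs_rest(
    y_true: Sequence[str],
    scores: np.ndarray,
    class_order: tuple[str, ...] = CLASSES,
) -> list[RocCurve]:
    """Per-class ROC from a score column per class; trapezoidal AUC."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] != len(class_order):
        raise ValueError("scores must have one column per class")
    curves: list[RocCurve] = []
    for i, label in enumerate(class_order):
        pos = y_true == label
        if pos.all() or not pos.any():
            warnings.warn(f"class {label} absent from one side: ROC undefined")
            curves.append(
                RocCurve(label, np.array([]), np.array([]), auc=float("nan"), defined=False)
            )
            continue
        fpr, tpr, _ = sk_roc_curve(pos.astype(int), scores[:, i])
        curves.append(RocCurve(label, fpr, tpr, auc=float(sk_auc(fpr, tpr))))
    return curves


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    model_factory: Callable[[], object],
    folds: FoldAssignment | None = None,
    class_order: tuple[str, ...] = CLASSES,
    ids: Sequence[str] | None = None,
    augmenter: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    seed: int = 0,
) -> EvalReport:
    """Run the k-fold protocol for one head.

    ``model_factory`` returns an unfitted estimator (anything implementing
    fit/predict; score columns are taken from predict_proba or
    decision_function).  ``augmenter``, if given, maps the *training-fold
    indices* to extra samples ``(X_extra, y_extra, source_idx)`` appended to
    the training set; the harness asserts every ``source_idx`` lies in the
    training fold, so augmentation can never touch test samples.  The
    partition property (disjoint folds covering every sample once) is
    asserted on every run.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if folds is None:
        folds = make_folds(y, 5, seed)
    if ids is None:
        ids = np.array([f"sample{i}" for i in range(len(y))])
    ids = np.asarray(ids)

    # partition property: every sample in exactly one test fold
    all_test = np.concatenate([folds.test_indices(f) for f in range(folds.n_folds)])
    if len(all_test) != len(y) or len(np.unique(all_test)) != len(y):
        raise AssertionError("fold assignment is not a partition of the samples")

    fold_cms: list[ConfusionMatrix] = []
    fold_metrics: list[MetricsReport] = []
    oof_scores = np.zeros((len(y), len(class_order)))
    for f in range(folds.n_folds):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        X_tr, y_tr = X[tr], y[tr]
        if augmenter is not None:
            X_extra, y_extra, source_idx = augmenter(tr)
            if not set(np.asarray(source_idx).tolist()) <= set(tr.tolist()):
                raise AssertionError(
                    "augmented samples derive from outside the training fold"
                )
            if len(X_extra):
                X_tr = np.vstack([X_tr, X_extra])
                y_tr = np.concatenate([y_tr, y_extra])
        try:
            model = model_factory()
            model = clone(model)
            model.fit(X_tr, y_tr)
            y_pred = model.predict(X[te])
            scores = _score_columns(model, X[te], class_order)
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {f}: {exc}") from exc
        oof_scores[te] = scores
        cm = confusion(y[te], y_pred, class_order)
        fold_cms.append(cm)
        fold_metrics.append(metrics_from_confusion(cm))

    mean_metrics = {
        "accuracy": float(np.mean([m.accuracy for m in fold_metrics])),
        **{
            m: float(np.mean([fm.macro[m] for fm in fold_metrics]))
            for m in METRIC_NAMES
            if m != "accuracy"
        },
    }
    pooled_cm = ConfusionMatrix(
        counts=np.sum([c.counts for c in fold_cms], axis=0), class_order=class_order
    )
    pooled = metrics_from_confusion(pooled_cm)
    roc = roc_one_vs_rest(y, oof_scores, class_order)
    defined = [r.auc for r in roc if r.defined]
    macro_auc = float(np.mean(defined)) if defined else float("nan")
    return EvalReport(
        fold_confusions=fold_cms,
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
        pooled=pooled,
        roc=roc,
        macro_auc=macro_auc,
    )


def _score_columns(model, X: np.ndarray, class_order: tuple[str, ...]) -> np.ndarray:
    """Per-class score columns aligned with ``class_order``."""
    if hasattr(model, "predict_proba"):
        raw = model.predict_proba(X)
    elif hasattr(model, "decision_function"):
        raw = model.decision_function(X)
        if raw.ndim == 1:
            raw = np.column_stack([-raw, raw])
    else:
        # fall back to one-hot of hard predictions
        pred = model.predict(X)
        raw = np.stack([(pred == c).astype(float) for c in model.classes_], axis=1)
    cols = np.zeros((len(X), len(class_order)))
    model_classes = list(getattr(model, "classes_", class_order))
    for j, c in enumerate(class_order):
        if c in model_classes:
            cols[:, j] = raw[:, model_classes.index(c)]
    return cols
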