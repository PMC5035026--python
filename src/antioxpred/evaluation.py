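"""Confusion-matrix metrics, ROC/AUC, and cross-validation orchestration.

The four headline metrics are sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP), accuracy Acc = (TP+TN)/(TP+FP+TN+FN) and Matthews'
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)).

Cross-validation uses stratified folds (per-class counts differ by at most
one across folds) and reports pooled (micro) metrics over the summed fold
confusion counts; the AUC is computed from the pooled out-of-fold scores.
Per-fold averaging is available as an option.  Any per-fold standardization
is fit on the training split only, so held-out samples never leak into the
scaler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification confusion counts (positive = antioxidant)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, Acc and MCC from confusion counts.

    If any MCC denominator factor is zero the MCC is defined as 0 and the
    returned dict carries ``mcc_undefined=1.0`` as a flag.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("Sn/Sp undefined: one class has no samples")
    sn = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    denom = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    out = {"Sn": sn, "Sp": sp, "Acc": acc}
    if denom == 0:
        out["MCC"] = 0.0
        out["mcc_undefined"] = 1.0
    else:
        out["MCC"] = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return out


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC curve points (1-Sp, Sn) and the area under the curve.

    The AUC equals the Mann-Whitney statistic: the probability that a random
    positive scores above a random negative, ties counted half.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


def stratified_kfold(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment: one fold index per sample.

    Folds partition the indices; per-class counts differ by at most one
    across folds.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} folds but only {n} samples")
    if k < 2:
        raise ValueError("need at least 2 folds")
    # shuffled per-class round-robin deal: works even when k exceeds the
    # smaller class size (down to leave-one-out), unlike StratifiedKFold
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    counter = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = counter % k
            counter += 1
    return assignment


@dataclass
class CvResult:
    """Outcome of a k-fold cross-validation run."""

    fold_counts: list[ConfusionCounts]
    scores: np.ndarray  # pooled out-of-fold positive-class probabilities
    labels: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)

    @property
    def pooled_counts(self) -> ConfusionCounts:
        total = ConfusionCounts(0, 0, 0, 0)
        for c in self.fold_counts:
            total = total + c
        return total

    def per_fold_metrics(self) -> list[dict[str, float]]:
        return [metrics(c) for c in self.fold_counts]


def cross_validate(
    model_factory: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    standardize: bool = True,
    threshold: float = 0.5,
) -> CvResult:
    """Stratified k-fold CV of a probabilistic binary classifier.

    ``model_factory`` returns a fresh unfitted estimator with ``fit`` and
    ``predict_proba``.  When ``standardize`` is on, a per-feature z-score
    scaler is fit inside each fold's training split only.  Pooled metrics are
    computed from summed fold counts; the AUC from pooled out-of-fold scores.
    A sample is called positive iff its fused probability >= ``threshold``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    assignment = stratified_kfold(y, k, seed)
    fold_counts: list[ConfusionCounts] = []
    scores = np.empty(len(y), dtype=float)
    for fold in range(k):
        test = assignment == fold
        train = ~test
        X_tr, X_te = X[train], X[test]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        model = model_factory()
        try:
            model.fit(X_tr, y[train])
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {fold}: {exc}") from exc
        proba = _positive_proba(model, X_te)
        scores[test] = proba
        pred = (proba >= threshold).astype(int)
        fold_counts.append(confusion_from_predictions(y[test], pred))
    result = CvResult(fold_counts, scores, y.copy())
    pooled = result.pooled_counts
    result.metrics = metrics(pooled)
    try:
        _, auc = roc_auc(scores, y)
        result.metrics["AUC"] = auc
    except ValueError:
        pass
    return result


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    """Positive-class probability column, robust to class ordering."""
    proba = model.predict_proba(X)
    classes = list(getattr(model, "classes_", [0, 1]))
    return np.asarray(proba)[:, classes.index(1)]
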