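"""Base-classifier registry, accuracy-ranked subset selection, and fusion.

The ensemble is built in two stages.  First every registered base classifier
is scored by stratified 10-fold cross-validated accuracy and ranked.  Then
nested prefixes of the ranking (top-1, top-2, ...) are each evaluated as an
average-probability ensemble, and the smallest prefix attaining the maximum
accuracy becomes the final model.  Fusion is the unweighted mean of the
members' positive-class probabilities; a sample is called positive iff the
mean is >= the decision threshold (default 0.5, ties positive).

The default registry holds ten members spanning tree, kernel, instance,
probabilistic and interval-voting families: random forest, a linear-kernel
SVM with probability calibration, 1-nearest-neighbor, a CART decision tree,
a categorical naive Bayes over quantile-binned features, an RBF-kernel SVM,
a depth-2 decision tree, AdaBoost over stumps, a natively implemented
voting-feature-intervals (VFI) classifier, and Gaussian naive Bayes.  Every
member exposes calibrated two-class probabilities so average-probability
fusion is well defined; hard voters (1-NN) contribute degenerate 0/1
probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import CategoricalNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import KBinsDiscretizer, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .evaluation import cross_validate, _positive_proba


class VotingFeatureIntervals(BaseEstimator, ClassifierMixin):
    """Voting-feature-intervals classifier for binary problems.

    For each feature and class, the closed interval [min, max] of that
    feature's training values within the class is recorded.  At prediction,
    each feature casts one unit vote split equally among the classes whose
    interval contains the test value (no vote if none contains it); votes are
    summed over features and normalized to probabilities.  A minimal standard
    form of the interval-voting family.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.lo_ = np.stack([X[y == c].min(axis=0) for c in self.classes_])
        self.hi_ = np.stack([X[y == c].max(axis=0) for c in self.classes_])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        k = len(self.classes_)
        votes = np.zeros((n, k))
        for j in range(d):
            inside = (X[:, [j]] >= self.lo_[:, j]) & (X[:, [j]] <= self.hi_[:, j])
            n_inside = inside.sum(axis=1)
            share = np.divide(
                inside.astype(float),
                n_inside[:, None],
                out=np.zeros((n, k)),
                where=n_inside[:, None] > 0,
            )
            votes += share
        totals = votes.sum(axis=1, keepdims=True)
        uniform = np.full((n, k), 1.0 / k)
        return np.divide(votes, totals, out=uniform, where=totals > 0)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class _QuietDiscretizer(KBinsDiscretizer):
    """Quantile binner that tolerates near-constant features silently."""

    def fit(self, X, y=None):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Bins whose width are too small")
            return super().fit(X, y)


@dataclass(frozen=True)
class ClassifierSpec:
    """A named base-classifier factory with its fixed hyperparameters."""

    name: str
    constructor: Callable[[int], object]
    hyperparameters: dict = field(default_factory=dict)

    def build(self, seed: int):
        return self.constructor(seed)


def default_registry() -> list[ClassifierSpec]:
    """The ten default base classifiers, in registry (tie-break) order."""
    return [
        ClassifierSpec(
            "RF",
            lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed),
            {"n_estimators": 100},
        ),
        ClassifierSpec(
            "SMO",
            lambda seed: CalibratedClassifierCV(
                SVC(kernel="linear", random_state=seed), method="sigmoid", ensemble=False
            ),
            {"kernel": "linear", "calibration": "sigmoid"},
        ),
        ClassifierSpec(
            "NNA",
            lambda seed: KNeighborsClassifier(n_neighbors=1),
            {"n_neighbors": 1},
        ),
        ClassifierSpec(
            "J48",
            lambda seed: DecisionTreeClassifier(random_state=seed),
            {},
        ),
        ClassifierSpec(
            "BN",
            lambda seed: Pipeline(
                [
                    (
                        "bins",
                        _QuietDiscretizer(
                            n_bins=5, encode="ordinal", strategy="quantile",
                            quantile_method="averaged_inverted_cdf",
                        ),
                    ),
                    ("nb", CategoricalNB(min_categories=5)),
                ]
            ),
            {"n_bins": 5},
        ),
        ClassifierSpec(
            "RBFNetwork",
            lambda seed: CalibratedClassifierCV(
                SVC(kernel="rbf", random_state=seed), method="sigmoid", ensemble=False
            ),
            {"kernel": "rbf", "calibration": "sigmoid"},
        ),
        ClassifierSpec(
            "DT",
            lambda seed: DecisionTreeClassifier(max_depth=2, random_state=seed),
            {"max_depth": 2},
        ),
        ClassifierSpec(
            "Adaboost",
            lambda seed: AdaBoostClassifier(n_estimators=50, random_state=seed),
            {"n_estimators": 50},
        ),
        ClassifierSpec("VFI", lambda seed: VotingFeatureIntervals(), {}),
        ClassifierSpec("NB", lambda seed: GaussianNB(), {}),
    ]


@dataclass(frozen=True)
class ClassifierRanking:
    """Classifier names ordered by non-increasing CV accuracy."""

    order: tuple[str, ...]
    accuracies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.order) != len(self.accuracies):
            raise ValueError("one accuracy per classifier required")
        if any(a < b - 1e-12 for a, b in zip(self.accuracies, self.accuracies[1:])):
            raise ValueError("accuracies must be non-increasing")


class AverageProbabilityEnsemble(BaseEstimator, ClassifierMixin):
    """Unweighted average of member positive-class probabilities."""

    def __init__(self, members: Sequence[tuple[str, object]] = ()):  # (name, estimator)
        self.members = list(members)

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.fitted_ = [(name, clone(est).fit(X, y)) for name, est in self.members]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "fitted_")
        pos = np.mean([_positive_proba(est, X) for _, est in self.fitted_], axis=0)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def rank_classifiers(
    registry: Sequence[ClassifierSpec],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    evaluator: Callable[[ClassifierSpec], float] | None = None,
) -> ClassifierRanking:
    """Rank base classifiers by CV accuracy (ties keep registry order).

    The default evaluator runs stratified k-fold CV with per-fold
    standardization; a stub evaluator can be injected for testing.  A spec
    whose training fails is dropped with a warning, never silently.
    """
    if len(registry) < 2:
        raise ValueError("need at least 2 classifier specs to rank")
    if evaluator is None:

        def evaluator(spec: ClassifierSpec) -> float:
            res = cross_validate(lambda: spec.build(seed), X, y, k=k, seed=seed)
            return res.metrics["Acc"]

    scored: list[tuple[str, float]] = []
    for spec in registry:
        try:
            scored.append((spec.name, float(evaluator(spec))))
        except Exception as exc:
            warnings.warn(f"classifier {spec.name!r} dropped: {exc}", stacklevel=2)
    if not scored:
        raise RuntimeError("every classifier failed evaluation")
    # stable sort keeps registry order within accuracy ties
    scored.sort(key=lambda t: -t[1])
    names, accs = zip(*scored)
    return ClassifierRanking(names, accs)


def select_subset_size(accuracies: Sequence[float]) -> int:
    """Smallest ensemble size attaining the maximum accuracy."""
    accs = np.asarray(accuracies, dtype=float)
    if accs.size == 0:
        raise ValueError("no subset accuracies supplied")
    return int(np.argmax(accs)) + 1


@dataclass
class EnsembleModel:
    """A fitted average-probability ensemble over selected features.

    ``feature_names`` is the full input schema the model was trained against;
    ``feature_indices`` are the columns of that schema the model consumes;
    ``standardizer`` is the per-feature z-scaler fit on the full training
    table; predictions are positive iff the fused probability is
    >= ``decision_threshold``.
    """

    member_names: list[str]
    members: list[object]
    feature_indices: np.ndarray
    feature_names: list[str]
    standardizer: StandardScaler
    decision_threshold: float = 0.5
    subset_curve: np.ndarray | None = None

    @property
    def selected_feature_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.feature_indices]

    def predict_proba(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        """Per-sample positive-class probability (mean over members)."""
        if not self.members:
            raise ValueError("ensemble has no members")
        if feature_names is not None and list(feature_names) != list(self.feature_names):
            raise ValueError("feature schema does not match the training schema")
        X = np.asarray(X, dtype=float)
        Xs = self.standardizer.transform(X[:, self.feature_indices])
        return np.mean([_positive_proba(m, Xs) for m in self.members], axis=0)

    def predict(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        return (self.predict_proba(X, feature_names) >= self.decision_threshold).astype(int)


def select_classifier_subset(
    ranking: ClassifierRanking,
    registry: Sequence[ClassifierSpec],
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    feature_indices: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    subset_evaluator: Callable[[int], float] | None = None,
) -> EnsembleModel:
    """Pick the accuracy-ranked classifier prefix that maximizes CV accuracy.

    For each prefix size j = 1..len(ranking) the average-probability ensemble
    of the top-j classifiers is scored (default: stratified k-fold CV); the
    smallest j attaining the maximum is kept and its members are refit on the
    full table.  ``subset_evaluator`` may be injected to supply per-size
    accuracies directly (e.g. from a precomputed table).
    """
    spec_by_name = {s.name: s for s in registry}
    X = np.asarray(X, dtype=float)
    if feature_indices is None:
        feature_indices = np.arange(X.shape[1])
    feature_indices = np.asarray(feature_indices, dtype=int)
    Xsel = X[:, feature_indices]

    def ensemble_factory(size: int) -> AverageProbabilityEnsemble:
        members = [(name, spec_by_name[name].build(seed)) for name in ranking.order[:size]]
        return AverageProbabilityEnsemble(members)

    if subset_evaluator is None:

        def subset_evaluator(size: int) -> float:
            res = cross_validate(lambda: ensemble_factory(size), Xsel, y, k=k, seed=seed)
            return res.metrics["Acc"]

    curve = []
    for size in range(1, len(ranking.order) + 1):
        try:
            curve.append(float(subset_evaluator(size)))
        except Exception as exc:
            raise RuntimeError(f"subset evaluation failed at size {size}: {exc}") from exc
    best = select_subset_size(curve)

    scaler = StandardScaler().fit(Xsel)
    Xs = scaler.transform(Xsel)
    fitted = []
    names = list(ranking.order[:best])
    for name in names:
        est = spec_by_name[name].build(seed)
        est.fit(Xs, y)
        fitted.append(est)
    return EnsembleModel(
        member_names=names,
        members=fitted,
        feature_indices=feature_indices,
        feature_names=list(feature_names),
        standardizer=scaler,
        subset_curve=np.asarray(curve),
    )


def fit_ensemble(
    member_names: Sequence[str],
    registry: Sequence[ClassifierSpec],
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    feature_indices: np.ndarray | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit a fixed-membership average-probability ensemble on the full table."""
    spec_by_name = {s.name: s for s in registry}
    X = np.asarray(X, dtype=float)
    if feature_indices is None:
        feature_indices = np.arange(X.shape[1])
    feature_indices = np.asarray(feature_indices, dtype=int)
    scaler = StandardScaler().fit(X[:, feature_indices])
    Xs = scaler.transform(X[:, feature_indices])
    fitted = [spec_by_name[n].build(seed).fit(Xs, y) for n in member_names]
    return EnsembleModel(
        member_names=list(member_names),
        members=fitted,
        feature_indices=feature_indices,
        feature_names=list(feature_names),
        standardizer=scaler,
    )
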