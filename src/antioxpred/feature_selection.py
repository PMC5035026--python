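"""Relief feature weighting and incremental feature selection (IFS).

Relief scores each feature by how well it separates nearest neighbors of
different classes: for each sampled instance the weight of feature p is
decreased by its scaled distance to the nearest same-class neighbor (the
nearest *hit*) and increased by its scaled distance to the nearest
other-class neighbor (the nearest *miss*), each divided by the number of
sampled instances m.  Features are min-max scaled internally so all
coordinate differences lie in [0, 1] and the weights are invariant under
strictly increasing affine rescalings of any feature.

IFS then walks the ranked list: prefixes of size 1..N are each scored by a
caller-supplied cross-validated accuracy function, and the smallest prefix
attaining the maximum accuracy is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class RankedFeatureList:
    """Feature indices ordered by non-increasing Relief weight.

    Ties are broken by ascending original index, so the ranking is a
    deterministic function of the weight vector.
    """

    order: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=int)
        weights = np.asarray(self.weights, dtype=float)
        if sorted(order.tolist()) != list(range(len(order))):
            raise ValueError("order is not a permutation of feature indices")
        if np.any(np.diff(weights) > 1e-12):
            raise ValueError("weights must be non-increasing along the ranking")
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return len(self.order)


@dataclass(frozen=True)
class IfsCurve:
    """Accuracy of every ranked-prefix feature subset, plus the selected size."""

    subset_sizes: np.ndarray
    accuracies: np.ndarray
    optimal_size: int

    def __post_init__(self) -> None:
        if len(self.subset_sizes) != len(self.accuracies):
            raise ValueError("one accuracy per subset size required")


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Per-feature min-max scaling to [0, 1]; constant features map to 0."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    return (X - lo) / safe


def relief_weights(
    X: np.ndarray,
    y: np.ndarray,
    m: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Relief feature weights for a binary-labeled sample matrix.

    For each of ``m`` sampled instances (default: every instance once, in an
    order shuffled by ``seed``) the nearest hit and nearest miss are found by
    Manhattan distance over the min-max scaled features, excluding the
    instance itself, with distance ties broken by lowest sample index.  Each
    feature's weight is updated by ``-diff(x, H)/m + diff(x, M)/m`` where
    ``diff`` is the absolute scaled coordinate difference.  An instance whose
    class has no other member contributes only its miss term (a warning is
    emitted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("Relief requires exactly two classes present")
    Xs = minmax_scale(X)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    if m is None:
        m = n
    sampled = order[np.arange(m) % n]  # each instance once when m == n

    # full pairwise Manhattan distances (n is modest in this problem)
    dist = np.abs(Xs[:, None, :] - Xs[None, :, :]).sum(axis=2)

    w = np.zeros(d)
    n_skipped_hits = 0
    for i in sampled:
        same = (y == y[i]).copy()
        same[i] = False
        other = y != y[i]
        if same.any():
            hit = _nearest(dist[i], same)
            w -= np.abs(Xs[i] - Xs[hit]) / m
        else:
            n_skipped_hits += 1
        miss = _nearest(dist[i], other)
        w += np.abs(Xs[i] - Xs[miss]) / m
    if n_skipped_hits:
        warnings.warn(
            f"Relief: {n_skipped_hits} instance(s) had no same-class neighbor; "
            "their hit terms were skipped",
            stacklevel=2,
        )
    return w


def _nearest(row: np.ndarray, mask: np.ndarray) -> int:
    """Index of the masked minimum, ties broken by lowest index."""
    candidates = np.flatnonzero(mask)
    return int(candidates[np.argmin(row[candidates])])


def rank_features(weights: Sequence[float]) -> RankedFeatureList:
    """Stable descending sort of feature indices by weight (ties: lower index first)."""
    weights = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite")
    order = np.argsort(-weights, kind="stable")
    return RankedFeatureList(order, weights[order])


def ifs_select(
    ranked: RankedFeatureList,
    scorer: Callable[[np.ndarray], float],
    max_size: int | None = None,
) -> IfsCurve:
    """Incremental feature selection over ranked prefixes.

    ``scorer`` maps a column-index array to a cross-validated accuracy in
    [0, 1].  Every prefix size 1..N (or up to ``max_size``) is evaluated; the
    smallest size attaining the maximum accuracy is selected.
    """
    N = len(ranked) if max_size is None else min(max_size, len(ranked))
    sizes = np.arange(1, N + 1)
    accs = np.empty(N)
    for j, size in enumerate(sizes):
        cols = ranked.order[:size]
        try:
            acc = float(scorer(cols))
        except Exception as exc:
            raise RuntimeError(f"scorer failed at prefix size {size}: {exc}") from exc
        if not 0.0 <= acc <= 1.0:
            raise ValueError(f"scorer returned {acc} outside [0, 1] at prefix size {size}")
        accs[j] = acc
    optimal = int(sizes[int(np.argmax(accs))])  # argmax returns first (smallest) maximizer
    return IfsCurve(sizes, accs, optimal)


def write_ranked_list(
    ranked: RankedFeatureList, feature_names: Sequence[str], path
) -> None:
    """Serialize a ranking as tab-delimited (rank, feature name, weight)."""
    with open(path, "w") as fh:
        fh.write("rank\tfeature\tweight\n")
        for r, (idx, w) in enumerate(zip(ranked.order, ranked.weights), start=1):
            fh.write(f"{r}\t{feature_names[idx]}\t{w:.10g}\n")


def write_ifs_curve(curve: IfsCurve, path) -> None:
    """Serialize an IFS curve as tab-delimited (subset size, accuracy)."""
    with open(path, "w") as fh:
        fh.write("subset_size\taccuracy\n")
        for size, acc in zip(curve.subset_sizes, curve.accuracies):
            fh.write(f"{size}\t{acc:.10g}\n")
        fh.write(f"# optimal_size\t{curve.optimal_size}\n")
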