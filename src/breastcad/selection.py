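"""ReliefF feature weighting, top-k ranking, and exhaustive subset search.

ReliefF scores each feature by how well it separates randomly sampled
instances from their nearest neighbours of other classes (misses)
relative to neighbours of the same class (hits):

    W(F) <- W(F) - sum_j diff(F, R_i, H_j) / (m k)
                 + sum_{C != class(R_i)} P(C) / (1 - P(class(R_i)))
                   * sum_j diff(F, R_i, M_j(C)) / (m k)

with diff the range-normalised absolute difference, m sampling
iterations and k neighbours per class.  Because diff is in [0, 1] the
weights always lie in [-1, 1].

The top-ranked features (eight by default) feed an exhaustive search
over all their nonempty subsets, each evaluated with the classifier
and resampling scheme of :mod:`breastcad.classify`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightVector",
    "feature_diff",
    "relieff_weights",
    "rank_and_select",
    "enumerate_subsets",
    "best_subset_search",
]


@dataclass
class WeightVector:
    weights: dict[str, float]
    k: int
    m: int
    seed: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights)


def _ranges(X: pd.DataFrame) -> pd.Series:
    return X.max(axis=0) - X.min(axis=0)


def feature_diff(
    feature: str, a: pd.Series, b: pd.Series, ranges: pd.Series
) -> float:
    """Range-normalised absolute difference of one feature, in [0, 1]."""
    if feature not in ranges.index:
        raise KeyError(f"unknown feature {feature!r}")
    rng = ranges[feature]
    if rng <= 0:
        return 0.0
    return float(abs(a[feature] - b[feature]) / rng)


def relieff_weights(
    X: pd.DataFrame,
    y: Sequence,
    k: int = 10,
    m: int | None = None,
    seed: int = 0,
) -> WeightVector:
    """ReliefF weights for every feature column.

    ``m`` defaults to the number of cases: every instance is sampled
    exactly once, in an order shuffled by ``seed``.  Neighbours are
    found by Manhattan distance on range-scaled features, consistent
    with the diff function.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    n, n_feat = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if (counts <= k).any():
        raise ValueError(
            f"insufficient class size for k={k}: every class needs > k members"
        )
    priors = dict(zip(classes, counts / n))

    ranges = _ranges(X).to_numpy()
    safe = np.where(ranges > 0, ranges, 1.0)
    Z = (X.to_numpy(dtype=float) - X.min(axis=0).to_numpy()) / safe
    Z[:, ranges <= 0] = 0.0

    rng = np.random.default_rng(seed)
    if m is None:
        m = n
        order = rng.permutation(n)
    else:
        order = rng.integers(0, n, size=m) if m > n else rng.permutation(n)[:m]

    W = np.zeros(n_feat)
    for idx in order:
        zi = Z[idx]
        dists = np.abs(Z - zi).sum(axis=1)
        dists[idx] = np.inf
        same = y == y[idx]
        hit_idx = np.where(same)[0]
        hits = hit_idx[np.argsort(dists[hit_idx], kind="stable")[:k]]
        W -= np.abs(Z[hits] - zi).sum(axis=0) / (m * k)
        for cls in classes:
            if cls == y[idx]:
                continue
            miss_idx = np.where(y == cls)[0]
            misses = miss_idx[np.argsort(dists[miss_idx], kind="stable")[:k]]
            w_cls = priors[cls] / (1.0 - priors[y[idx]])
            W += w_cls * np.abs(Z[misses] - zi).sum(axis=0) / (m * k)

    return WeightVector(
        weights=dict(zip(X.columns, W)), k=k, m=int(m), seed=seed
    )


def rank_and_select(weights: WeightVector, n_keep: int = 8) -> list[str]:
    """Top ``n_keep`` features by weight; ties broken by name order."""
    items = sorted(weights.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    if n_keep > len(items):
        raise ValueError("n_keep exceeds the number of features")
    return [name for name, _ in items[:n_keep]]


def enumerate_subsets(features: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^n - 1 nonempty subsets, ordered by size then position."""
    features = list(features)
    if not features:
        raise ValueError("feature list must be non-empty")
    if len(features) > 20:
        raise ValueError("subset explosion: refusing to enumerate > 2^20 subsets")
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(features) + 1):
        subsets.extend(combinations(features, size))
    return subsets


def best_subset_search(
    X: pd.DataFrame,
    y: Sequence,
    subsets: Sequence[Sequence[str]],
    evaluate: Callable[[pd.DataFrame, Sequence], "object"],
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Evaluate every subset; return the best and the full report.

    ``evaluate(X_subset, y)`` must return an object with ``accuracy``,
    ``sensitivity`` and ``specificity`` attributes (an
    :class:`breastcad.classify.EvalResult`).  The best subset maximises
    accuracy; ties break on higher sensitivity, then smaller size.
    """
    if not subsets:
        raise ValueError("no subsets supplied")
    records = []
    for subset in subsets:
        subset = tuple(subset)
        res = evaluate(X.loc[:, list(subset)], y)
        records.append(
            {
                "subset": ",".join(subset),
                "size": len(subset),
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
            }
        )
    report = pd.DataFrame.from_records(records)
    best_i = report.sort_values(
        by=["accuracy", "sensitivity", "size"],
        ascending=[False, False, True],
        kind="stable",
    ).index[0]
    best = tuple(report.loc[best_i, "subset"].split(","))
    return best, report
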