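"""Modified weighted k-nearest-neighbour classification with LOOCV.

The classifier extends plain KNN along four grid-searched axes:

* neighbour scope — the k nearest overall, or the k nearest *per class*;
* metric — Manhattan or Euclidean, after per-feature weighting;
* feature weighting — uniform, or signal-to-noise ratio
  |μ₁ − μ₂| / (σ₁ + σ₂) normalized to sum 1 (wwKNN-style importance);
* vote weighting — uniform, inverse distance, or the range function
  (d_max − (d_i − d_min)) / d_max over the neighbour set.

Evaluation is leave-one-out cross-validation; SNR weights are recomputed
inside every fold so the held-out sample never influences them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KNNParams",
    "CVResult",
    "snr_weights",
    "knn_predict",
    "loocv",
    "grid_search",
    "default_grid",
]

_EPS = 1e-12


@dataclass(frozen=True)
class KNNParams:
    k: int = 1
    k_scope: str = "all_neighbors"        # or "per_class"
    metric: str = "manhattan"             # or "euclidean"
    feature_weighting: str = "uniform"    # or "snr"
    vote_weighting: str = "uniform"       # or "inverse_distance", "range_function"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k_scope not in ("all_neighbors", "per_class"):
            raise ValueError(f"unknown k_scope {self.k_scope!r}")
        if self.metric not in ("manhattan", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.feature_weighting not in ("uniform", "snr"):
            raise ValueError(f"unknown feature_weighting {self.feature_weighting!r}")
        if self.vote_weighting not in ("uniform", "inverse_distance", "range_function"):
            raise ValueError(f"unknown vote_weighting {self.vote_weighting!r}")


@dataclass
class CVResult:
    accuracy: float            # percent
    predictions: list          # per-fold predicted labels
    truth: list
    params: KNNParams
    n: int                     # folds evaluated
    n_failed: int = 0          # degenerate folds excluded


def snr_weights(train: np.ndarray, labels: Sequence) -> np.ndarray:
    """Per-feature SNR weights |μ₁−μ₂|/(σ₁+σ₂), normalized to sum 1.

    Features that are constant within both classes and share the class means
    get weight 0.  Requires exactly two classes with ≥ 2 samples each.
    """
    X = np.asarray(train, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"snr_weights needs exactly 2 classes, got {classes.size}")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    num = np.abs(a.mean(axis=0) - b.mean(axis=0))
    den = a.std(axis=0, ddof=1) + b.std(axis=0, ddof=1)
    w = np.zeros(X.shape[1])
    nz = den > 0
    w[nz] = num[nz] / den[nz]
    w[(~nz) & (num > 0)] = num[(~nz) & (num > 0)] / _EPS  # perfectly clean split
    total = w.sum()
    return w / total if total > 0 else np.full(X.shape[1], 1.0 / X.shape[1])


def _distances(
    train: np.ndarray, test: np.ndarray, w: np.ndarray, metric: str
) -> np.ndarray:
    diff = np.abs(train - test[None, :]) * w[None, :]
    if metric == "manhattan":
        return diff.sum(axis=1)
    return np.sqrt((diff**2).sum(axis=1))


def _vote_weights(d: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "uniform":
        return np.ones_like(d)
    if scheme == "inverse_distance":
        return 1.0 / np.maximum(d, _EPS)
    dmax, dmin = d.max(), d.min()
    if dmax <= 0:  # all neighbours equidistant at 0 → uniform
        return np.ones_like(d)
    return (dmax - (d - dmin)) / dmax


def knn_predict(
    train: np.ndarray,
    labels: Sequence,
    test: np.ndarray,
    p: KNNParams,
    feature_weights: np.ndarray | None = None,
):
    """Predict one test vector; returns (label, vote score per class).

    Neighbour ties at equal distance are broken by training index (stable
    sort); vote ties go to the lexicographically smaller label.
    """
    X = np.asarray(train, dtype=np.float64)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if feature_weights is None:
        if p.feature_weighting == "snr":
            feature_weights = snr_weights(X, y)
        else:
            feature_weights = np.ones(X.shape[1])
    d = _distances(X, np.asarray(test, dtype=np.float64), feature_weights, p.metric)
    classes = sorted(np.unique(y).tolist())
    if p.k_scope == "all_neighbors":
        if p.k > len(y):
            raise ValueError(f"k={p.k} exceeds {len(y)} training samples")
        nb = np.argsort(d, kind="stable")[: p.k]
    else:
        parts = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            if p.k > idx.size:
                raise ValueError(f"k={p.k} exceeds class {c!r} size {idx.size}")
            parts.append(idx[np.argsort(d[idx], kind="stable")[: p.k]])
        nb = np.concatenate(parts)
    vw = _vote_weights(d[nb], p.vote_weighting)
    scores = {c: float(vw[y[nb] == c].sum()) for c in classes}
    # arg-max with tie → lexicographically smaller label
    top = max(scores.values())
    winners = [c for c in classes if scores[c] == top]
    return min(winners), scores


def loocv(data: np.ndarray, labels: Sequence, p: KNNParams) -> CVResult:
    """Leave-one-out cross-validation; SNR weights recomputed per fold."""
    X = np.asarray(data, dtype=np.float64)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    preds, truth = [], []
    failed = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            yhat, _ = knn_predict(X[mask], y[mask], X[i], p)
        except ValueError:
            failed += 1
            continue
        preds.append(yhat)
        truth.append(y[i])
    evaluated = len(preds)
    correct = sum(int(a == b) for a, b in zip(preds, truth))
    acc = 100.0 * correct / evaluated if evaluated else 0.0
    return CVResult(acc, preds, truth, p, evaluated, failed)


def default_grid(ks: Iterable[int] = (1, 3, 5, 7, 9)) -> list[KNNParams]:
    """The full exhaustive parameter grid in canonical enumeration order."""
    out = []
    for k, scope, metric, fw, vw in itertools.product(
        ks,
        ("all_neighbors", "per_class"),
        ("manhattan", "euclidean"),
        ("uniform", "snr"),
        ("uniform", "inverse_distance", "range_function"),
    ):
        out.append(KNNParams(k, scope, metric, fw, vw))
    return out


def grid_search(
    data: np.ndarray, labels: Sequence, param_space: Sequence[KNNParams] | None = None
) -> tuple[CVResult, pd.DataFrame]:
    """LOOCV every parameter combination; best by accuracy, ties → first in
    enumeration order.  Returns (best result, full results table)."""
    space = list(param_space) if param_space is not None else default_grid()
    if not space:
        raise ValueError("empty parameter space")
    rows, results = [], []
    for p in space:
        try:
            res = loocv(data, labels, p)
        except ValueError:
            continue
        results.append(res)
        rows.append(
            {
                "k": p.k, "k_scope": p.k_scope, "metric": p.metric,
                "feature_weighting": p.feature_weighting,
                "vote_weighting": p.vote_weighting,
                "accuracy": res.accuracy, "n": res.n,
            }
        )
    if not results:
        raise ValueError("no evaluable parameter combination")
    best = max(range(len(results)), key=lambda i: results[i].accuracy)
    return results[best], pd.DataFrame(rows)
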