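"""Optional off-the-shelf baseline classifiers behind the same LOOCV surface.

Thin adapters only: linear discriminant analysis (scikit-learn, least-squares
solver with auto shrinkage) and LightGBM.  They exist for comparison against
the modified KNN and are not part of the core pipeline.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .classifier import CVResult, KNNParams

__all__ = ["baseline_loocv"]


def _lda():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def _lgbm():
    from lightgbm import LGBMClassifier

    # min_child_samples lowered so trees can split on LOOCV-sized cohorts
    return LGBMClassifier(
        n_estimators=50, min_child_samples=2, verbose=-1, n_jobs=1, random_state=0
    )


def baseline_loocv(data: np.ndarray, labels: Sequence, algorithm: str) -> CVResult:
    """Leave-one-out cross-validation of an off-the-shelf baseline
    ('lda' or 'lgbm')."""
    makers = {"lda": _lda, "lgbm": _lgbm}
    if algorithm not in makers:
        raise ValueError(f"unknown baseline {algorithm!r}; choose from {sorted(makers)}")
    X = np.asarray(data, dtype=np.float64)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    preds, truth, failed = [], [], 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            failed += 1
            continue
        model = makers[algorithm]()
        model.fit(X[mask], y[mask])
        preds.append(model.predict(X[i : i + 1])[0])
        truth.append(y[i])
    correct = sum(int(a == b) for a, b in zip(preds, truth))
    acc = 100.0 * correct / len(preds) if preds else 0.0
    return CVResult(acc, preds, truth, KNNParams(), len(preds), failed)
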