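"""Handcrafted-feature random-forest baseline.

A classical activity-recognition pipeline for comparison with the CNN:
each 2-s window is summarised by standard time-domain statistics and fed
to a random forest.  Per arm (3 channels) the feature vector holds 21
values: mean, SD, min, max and RMS for each channel (15), the signal
magnitude area (mean Σ|a_c|, 1), the three pairwise channel
correlations, and the mean and SD of the acceleration magnitude |a|.
For the combined 6-channel variant the 21 features are computed per arm
(42) plus the 9 cross-arm channel correlations.

The forest (500 trees, sqrt-features per split, fixed seed) is evaluated
on the *same* split plan as the CNN so the two models are compared on
matching folds.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline

from .evaluate import SplitPlan, compute_metrics

FEATURES_PER_ARM = 21


def _arm_features(w: np.ndarray) -> np.ndarray:
    """21 time-domain features of one arm's (T, 3) window."""
    mean = w.mean(axis=0)
    sd = w.std(axis=0)
    wmin = w.min(axis=0)
    wmax = w.max(axis=0)
    rms = np.sqrt(np.mean(w ** 2, axis=0))
    sma = np.mean(np.sum(np.abs(w), axis=1))
    corrs = []
    for i in range(3):
        for j in range(i + 1, 3):
            corrs.append(_safe_corr(w[:, i], w[:, j]))
    mag = np.linalg.norm(w, axis=1)
    return np.concatenate([mean, sd, wmin, wmax, rms, [sma], corrs,
                           [mag.mean(), mag.std()]])


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant channel: correlation defined as 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def extract_features(window: np.ndarray) -> np.ndarray:
    """Feature vector of one (60, C) window, C = 3 or 6.

    Deterministic; constant channels get SD 0 and correlation 0 (with a
    warning).  NaN input is rejected.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] not in (3, 6):
        raise ValueError("expected a (T, 3) or (T, 6) window")
    if np.isnan(w).any():
        raise ValueError("window contains NaN")
    if w.shape[1] == 3:
        return _arm_features(w)
    f1 = _arm_features(w[:, :3])
    f2 = _arm_features(w[:, 3:])
    cross = [_safe_corr(w[:, i], w[:, 3 + j]) for i in range(3) for j in range(3)]
    return np.concatenate([f1, f2, cross])


class WindowFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: (N, T, C) windows → (N, n_features)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([extract_features(w) for w in X])


class RandomForestBaseline(BaseEstimator):
    """Feature extraction + random forest as one sklearn estimator."""

    def __init__(self, n_estimators=500, seed=0):
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X, y):
        self.pipeline_ = Pipeline([
            ("features", WindowFeatureExtractor()),
            ("rf", RandomForestClassifier(n_estimators=self.n_estimators,
                                          max_features="sqrt",
                                          random_state=self.seed)),
        ])
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["rf"].classes_
        return self

    def predict(self, X):
        return self.pipeline_.predict(X)

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(X)


def run_baseline(dataset, plan: SplitPlan, n_estimators: int = 500,
                 seed: int = 0):
    """Evaluate the RF baseline on each fold of an existing split plan.

    Reuses the plan built for the CNN so both models see identical folds;
    the scaler is refitted on each fold's training windows.  Returns
    per-fold (train MetricSet, validation MetricSet) pairs.
    """
    from .preprocess import RobustWindowScaler

    results = []
    for train_idx, test_idx in plan:
        if len(set(train_idx) & set(test_idx)):
            raise ValueError("split plan has overlapping train/test folds")
        scaler = RobustWindowScaler().fit(dataset.windows[train_idx])
        Xtr = scaler.transform(dataset.windows[train_idx])
        Xte = scaler.transform(dataset.windows[test_idx])
        rf = RandomForestBaseline(n_estimators=n_estimators, seed=seed)
        rf.fit(Xtr, dataset.y[train_idx])
        results.append((
            compute_metrics(dataset.y[train_idx], rf.predict(Xtr)),
            compute_metrics(dataset.y[test_idx], rf.predict(Xte)),
        ))
    return results
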