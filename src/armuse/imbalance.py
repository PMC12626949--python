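"""From-scratch SMOTE oversampling of the minority (functional) class.

Severely impaired subjects use the paretic arm for as little as 3–8% of
the recording, which starves the classifier of functional examples.
SMOTE (synthetic minority oversampling) interpolates new minority
samples between existing ones: each synthetic window is
``x_i + u · (x_nn − x_i)`` with ``u ~ Uniform(0, 1)`` and ``x_nn`` one of
``x_i``'s k nearest minority neighbours (Euclidean distance in the
flattened, scaled window space).  Rebalancing targets a
minority/majority ratio of 0.5 by default, i.e. a minority fraction of
1/3 of the training set.

Applied to the *training* split only — never to validation or test data.
Synthesis provenance (parent index, neighbour index, interpolation u) is
returned so tests can verify the geometry against a brute-force
neighbour search.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .preprocess import WindowedDataset


@dataclass
class SmoteConfig:
    target_ratio: float = 0.5
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be ≥ 1")


@dataclass
class SmoteProvenance:
    """Where each synthetic sample came from: parents and mixing weight."""

    parent_idx: np.ndarray
    neighbor_idx: np.ndarray
    u: np.ndarray


def smote_synthesize(minority_windows: np.ndarray, n_new: int, k: int = 5,
                     seed: int = 0, return_provenance: bool = False):
    """Create ``n_new`` synthetic minority windows by neighbour interpolation.

    Windows are flattened for the neighbour search and the synthetics are
    reshaped back to window shape.  Deterministic for a fixed seed.
    Raises if the minority class has ≤ k members (no k neighbours exist).
    """
    X = np.asarray(minority_windows, dtype=float)
    n_min = len(X)
    if n_min <= k:
        raise ValueError(f"minority count {n_min} must exceed k={k}")
    if n_new < 0:
        raise ValueError("n_new must be nonnegative")
    shape = X.shape[1:]
    flat = X.reshape(n_min, -1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(flat)  # +1: self included
    neigh = nn.kneighbors(flat, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    parents = rng.integers(0, n_min, size=n_new)
    choice = rng.integers(0, k, size=n_new)
    u = rng.random(n_new)
    nn_idx = neigh[parents, choice]
    synth = flat[parents] + u[:, None] * (flat[nn_idx] - flat[parents])
    synth = synth.reshape((n_new,) + shape)
    if return_provenance:
        return synth, SmoteProvenance(parent_idx=parents, neighbor_idx=nn_idx, u=u)
    return synth


def rebalance_training_set(dataset: WindowedDataset,
                           config: SmoteConfig | None = None) -> WindowedDataset:
    """Oversample the minority class of a training set up to the target ratio.

    If minority/majority is already at or above ``target_ratio`` the set
    is returned unchanged; otherwise exactly
    ``ceil(target_ratio · n_majority) − n_minority`` synthetic windows are
    added, leaving the minority fraction at
    ``target_ratio / (1 + target_ratio)`` (e.g. 33.3% for the default
    ratio 0.5).  Synthetic windows carry the subject id ``"smote"`` so
    leakage checks can identify them.
    """
    config = config or SmoteConfig()
    y = dataset.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cannot rebalance a single-class training set")
    min_cls = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min / n_maj >= config.target_ratio:
        return dataset
    n_new = ceil(config.target_ratio * n_maj) - n_min
    synth = smote_synthesize(dataset.windows[y == min_cls], n_new,
                             k=config.k_neighbors, seed=config.seed)
    return WindowedDataset(
        windows=np.concatenate([dataset.windows, synth]),
        y=np.concatenate([y, np.full(n_new, min_cls, dtype=y.dtype)]),
        subject_ids=np.concatenate([dataset.subject_ids,
                                    np.full(n_new, "smote")]),
        variant=dataset.variant,
    )


class WindowSMOTE(BaseEstimator):
    """Estimator-style wrapper: ``fit_resample(X, y)`` à la imblearn.

    Parameters as :class:`SmoteConfig`.  ``fit_resample`` returns the
    augmented ``(X, y)``; provenance of the last call is stored in
    ``provenance_`` when the minority class was actually resampled.
    """

    def __init__(self, target_ratio=0.5, k_neighbors=5, seed=0):
        self.target_ratio = target_ratio
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("cannot rebalance a single-class training set")
        n_min, n_maj = counts.min(), counts.max()
        min_cls = classes[np.argmin(counts)]
        self.provenance_ = None
        if n_min / n_maj >= self.target_ratio:
            return X, y
        n_new = ceil(self.target_ratio * n_maj) - n_min
        synth, prov = smote_synthesize(X[y == min_cls], n_new,
                                       k=self.k_neighbors, seed=self.seed,
                                       return_provenance=True)
        self.provenance_ = prov
        return (np.concatenate([X, synth]),
                np.concatenate([y, np.full(n_new, min_cls, dtype=y.dtype)]))
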