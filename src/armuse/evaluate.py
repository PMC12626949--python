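"""Split plans, classification metrics, aggregation and paired statistics.

Two evaluation schemes are supported, mirroring how within- and
across-subject generalisation are assessed in wearable-sensor studies:

* **intrasubject**: each subject's windows are split into 5 folds
  (stratified by class when feasible); the model trains on 4 and is
  validated on the fifth, rotating through all folds;
* **intersubject (LOSO)**: leave-one-subject-out — the model trains on
  all subjects but one and is validated on the held-out subject, once
  per subject.  A leakage guard asserts train/test subject disjointness
  on every fold.

Metrics are accuracy and per-class F1 (functional = positive class),
kept together with the raw confusion counts so every number is
reproducible from the tallies.  Aggregation reports mean ± SD (n−1
denominator) over folds/subjects.  Train-vs-validation comparisons use a
two-sided paired t-test and Cohen's d with a pairing-corrected 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass
class SplitPlan:
    """A list of (train_idx, test_idx) folds under one scheme."""

    scheme: str  # "kfold" | "loso"
    folds: list
    seed: int | None = None
    subjects: list = field(default_factory=list)  # per-fold held-out subject (loso)

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


@dataclass
class MetricSet:
    """Accuracy and per-class F1 with the underlying confusion counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def f1_functional(self) -> float:
        return _f1(self.tp, self.fp, self.fn)

    @property
    def f1_nonfunctional(self) -> float:
        # swap the positive class: TN become TP, FN/FP swap roles
        return _f1(self.tn, self.fn, self.fp)

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "f1_functional": self.f1_functional,
                "f1_nonfunctional": self.f1_nonfunctional,
                "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("F1 undefined (class absent from truth and prediction); "
                      "reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return 2 * tp / denom


@dataclass
class ComparisonStats:
    """Paired train-vs-validation comparison for one metric."""

    mean_diff: float
    p_value: float  # NaN when the differences have zero variance
    cohens_d: float
    ci95: tuple
    d_z: float  # alternative convention: mean diff / sd(diff)
    n: int


def make_intrasubject_folds(n_windows: int, y=None, k: int = 5,
                            seed: int = 0) -> SplitPlan:
    """K-fold plan over one subject's windows (default 5 folds).

    Stratified by label when ``y`` is given and both classes have at
    least ``k`` members; otherwise plain shuffled K-fold.  Test sets
    partition the index set with sizes differing by at most one.
    """
    if n_windows < k:
        raise ValueError(f"need at least k={k} windows, got {n_windows}")
    idx = np.arange(n_windows)
    stratify = False
    if y is not None:
        y = np.asarray(y)
        _, counts = np.unique(y, return_counts=True)
        stratify = len(counts) == 2 and counts.min() >= k
    if stratify:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in splitter.split(idx, y)]
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in splitter.split(idx)]
    return SplitPlan(scheme="kfold", folds=folds, seed=seed)


def make_loso_folds(subject_ids) -> SplitPlan:
    """Leave-one-subject-out plan: one fold per subject.

    Fold i tests exactly subject i's windows and trains on everyone
    else's; train and test subject sets are disjoint by construction and
    re-asserted here.
    """
    subject_ids = np.asarray(subject_ids)
    subjects = sorted(set(subject_ids.tolist()))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    folds = []
    for s in subjects:
        test = np.flatnonzero(subject_ids == s)
        train = np.flatnonzero(subject_ids != s)
        assert not set(subject_ids[train]) & set(subject_ids[test]), \
            "LOSO leakage: subject on both sides of a fold"
        folds.append((train, test))
    return SplitPlan(scheme="loso", folds=folds, subjects=subjects)


def assert_no_subject_leakage(plan: SplitPlan, subject_ids) -> None:
    """Guard: no subject appears in both train and test of any fold."""
    subject_ids = np.asarray(subject_ids)
    for train, test in plan:
        overlap = set(subject_ids[train]) & set(subject_ids[test])
        if overlap:
            raise AssertionError(f"subject leakage across a fold: {overlap}")


def compute_metrics(y_true, y_pred) -> MetricSet:
    """Confusion-count metrics with functional (1) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return MetricSet(tp=tp, fp=fp, tn=tn, fn=fn)


def aggregate(values, level: str = "fold") -> tuple:
    """Mean ± SD of a metric across folds or subjects.

    ``values`` is either a flat list (one entry per fold/subject) or, for
    two-stage intrasubject aggregation, a list of per-subject lists whose
    fold means are averaged first.  SD uses the n−1 denominator; a single
    entry yields SD 0 with a warning.
    """
    values = list(values)
    if not values:
        raise ValueError("nothing to aggregate")
    if isinstance(values[0], (list, tuple, np.ndarray)):
        values = [float(np.mean(v)) for v in values]
    arr = np.asarray(values, dtype=float)
    if len(arr) == 1:
        warnings.warn("SD of a single value is undefined; reporting 0",
                      RuntimeWarning, stacklevel=2)
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def paired_comparison(train_scores, val_scores) -> ComparisonStats:
    """Two-sided paired t-test plus Cohen's d for train vs validation.

    Cohen's d uses the pooled-SD convention,
    ``d = mean(train − val) / sqrt((sd_train² + sd_val²)/2)``, with a 95%
    CI ``d ± 1.96·se``, ``se = sqrt(1/n + d²/(2n)) · sqrt(2(1 − r))``
    where r is the pairing correlation.  The alternative convention
    ``d_z = mean(diff)/sd(diff)`` is reported alongside.  Zero-variance
    differences make the t-test undefined; p is then NaN.
    """
    tr = np.asarray(train_scores, dtype=float)
    va = np.asarray(val_scores, dtype=float)
    if tr.shape != va.shape or tr.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    n = len(tr)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = tr - va
    sd_diff = diff.std(ddof=1)
    if sd_diff == 0:
        p = np.nan
    else:
        p = float(stats.ttest_rel(tr, va).pvalue)
    sd_tr, sd_va = tr.std(ddof=1), va.std(ddof=1)
    pooled = np.sqrt((sd_tr ** 2 + sd_va ** 2) / 2)
    d = float(diff.mean() / pooled) if pooled > 0 else 0.0
    if sd_tr > 0 and sd_va > 0:
        r = float(np.corrcoef(tr, va)[0, 1])
    else:
        r = 0.0
    se = np.sqrt(1 / n + d ** 2 / (2 * n)) * np.sqrt(max(2 * (1 - r), 0.0))
    d_z = float(diff.mean() / sd_diff) if sd_diff > 0 else 0.0
    return ComparisonStats(mean_diff=float(diff.mean()), p_value=p,
                           cohens_d=d, ci95=(d - 1.96 * se, d + 1.96 * se),
                           d_z=d_z, n=n)
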