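"""End-to-end runs: cohort → windows → (SMOTE) → CNN/RF → metrics.

This module sequences the pipeline the way the underlying study design
demands: per subject, both arms are down-sampled to 30 Hz and axis-
harmonised; the sensor clock is aligned through the five sync-prelude
peaks; per-frame annotator votes are collapsed by majority and
transferred onto the sensor timeline; unknown samples (including the
prelude, recorded before the sensor is attached) are excluded; the rest
is windowed into 2-s instances under the requested variant.  Evaluation
then runs either 5-fold intrasubject or leave-one-subject-out
cross-validation, fitting the robust scaler — and optionally SMOTE — on
each fold's training data only.  Every fold records a ``guards`` entry
proving that scaler and SMOTE saw training indices only and that LOSO
folds never share a subject.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from . import model as mdl
from .imbalance import SmoteConfig, rebalance_training_set
from .preprocess import (
    TARGET_RATE_HZ,
    LabelTrack,
    RobustWindowScaler,
    WindowedDataset,
    assemble_variant,
    consensus_labels,
    harmonize_axes,
    resample_to_30hz,
    transfer_labels,
)
from .sensor_io import (
    UNKNOWN,
    RawTrace,
    align_clocks,
    detect_sync_peaks,
    read_accel_csv,
    read_annotation_csv,
)
from .synth import PRELUDE_S, SyntheticSubject

VARIANTS = ("paretic", "nonparetic", "combined")


def load_cohort(cohort_dir) -> list[SyntheticSubject]:
    """Load a cohort written by :func:`armuse.synth.generate_cohort`."""
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    subjects = []
    for sid, meta in sorted(manifest["subjects"].items()):
        d = cohort_dir / sid
        rate = meta["rate_hz"]
        side = meta["paretic_side"]
        traces = {}
        for role in ("paretic", "nonparetic"):
            arm_side = side if role == "paretic" else \
                ("right" if side == "left" else "left")
            traces[role] = read_accel_csv(d / f"{role}.csv", side=arm_side,
                                          role=role, rate_hz=rate)
        ann = read_annotation_csv(d / "annotations.csv", frame_rate_hz=rate)
        subjects.append(SyntheticSubject(subject_id=sid, rate_hz=rate,
                                         paretic_side=side, traces=traces,
                                         truths={}, annotations=ann))
    return subjects


def _sync_clock_map(trace: RawTrace):
    """Identity-calibrated clock map from the trace's own sync prelude.

    The five prelude peaks are detected on the z axis within the
    calibration window; the video-side reversal marks carry the same
    times here (the synthetic annotations live on the sensor clock), so
    aligning the two recovers the identity map while still exercising
    the detector and the least-squares fit.
    """
    n_pre = int(round((PRELUDE_S + 2.0) * trace.rate_hz))
    crop = RawTrace(t=trace.t[:n_pre], a=trace.a[:n_pre],
                    rate_hz=trace.rate_hz, side=trace.side, role=trace.role)
    peaks = detect_sync_peaks(crop)
    return align_clocks(peaks, peaks)


def preprocess_subject(subj: SyntheticSubject, variant: str,
                       mirror_axis: str = "x", window_s: float = 2.0,
                       use_sync: bool = True) -> WindowedDataset:
    """One subject's raw session → a windowed dataset in one variant."""
    arms = {}
    for role in ("paretic", "nonparetic"):
        trace = subj.traces[role]
        clock = _sync_clock_map(trace) if use_sync else None
        trace30 = harmonize_axes(resample_to_30hz(trace), mirror_axis)
        votes = consensus_labels(subj.annotations, role)
        if clock is None:
            from .sensor_io import ClockMap
            clock = ClockMap(offset_s=0.0, scale=1.0)
        labels30 = transfer_labels(votes, clock, len(trace30))
        # the prelude precedes attachment: exclude it from training data
        n_pre = int(round(PRELUDE_S * TARGET_RATE_HZ))
        labels = labels30.labels.copy()
        labels[:n_pre] = UNKNOWN
        arms[role] = (trace30, LabelTrack(rate_hz=TARGET_RATE_HZ, labels=labels))
    return assemble_variant(arms["paretic"], arms["nonparetic"], variant,
                            subject_id=subj.subject_id, window_s=window_s)


def preprocess_cohort(subjects, variant: str, **kw) -> WindowedDataset:
    return WindowedDataset.concatenate(
        [preprocess_subject(s, variant, **kw) for s in subjects])


# ----------------------------------------------------------- fold evaluation

@dataclass
class FoldResult:
    train: ev.MetricSet
    val: ev.MetricSet
    history: dict
    guards: dict


def evaluate_cnn_on_plan(dataset: WindowedDataset, plan: ev.SplitPlan,
                         train_cfg: mdl.TrainConfig | None = None,
                         smote: SmoteConfig | None = None) -> list[FoldResult]:
    """Train and score the CNN on every fold of a split plan.

    Per fold: robust scaler fitted on the training windows only; SMOTE
    (if requested) applied to the scaled training set only; the held-out
    fold serves as the validation set monitored by the training
    callbacks, matching the train/validation reporting convention of the
    cross-validated study design.  Training metrics are computed on the
    real (non-synthetic) training windows.
    """
    train_cfg = train_cfg or mdl.TrainConfig()
    if plan.scheme == "loso":
        ev.assert_no_subject_leakage(plan, dataset.subject_ids)
    results = []
    for fold_i, (train_idx, test_idx) in enumerate(plan):
        scaler = RobustWindowScaler().fit(dataset.windows[train_idx])
        train_set = WindowedDataset(scaler.transform(dataset.windows[train_idx]),
                                    dataset.y[train_idx],
                                    dataset.subject_ids[train_idx],
                                    dataset.variant)
        X_val = scaler.transform(dataset.windows[test_idx])
        y_val = dataset.y[test_idx]
        n_real = len(train_set)
        guards = {
            "scaler_fit_on": "train",
            "scaler_fit_n": int(len(train_idx)),
            "train_test_overlap": int(len(set(train_idx) & set(test_idx))),
            "smote_applied_to": None,
            "val_label_counts_before": np.bincount(y_val, minlength=2).tolist(),
        }
        if smote is not None:
            train_set = rebalance_training_set(train_set, smote)
            guards["smote_applied_to"] = "train"
            guards["smote_added"] = int(len(train_set) - n_real)
        cfg = mdl.TrainConfig(**{**asdict(train_cfg),
                                 "seed": (train_cfg.seed + fold_i) % 2_147_483_647})
        trained = mdl.train(train_set.windows, train_set.y, X_val, y_val, cfg)
        y_pred_tr = mdl.classify(
            mdl.predict_proba(trained, train_set.windows[:n_real]))
        y_pred_va = mdl.classify(mdl.predict_proba(trained, X_val))
        guards["val_label_counts_after"] = np.bincount(y_val, minlength=2).tolist()
        results.append(FoldResult(
            train=ev.compute_metrics(train_set.y[:n_real], y_pred_tr),
            val=ev.compute_metrics(y_val, y_pred_va),
            history=trained.history,
            guards=guards,
        ))
    return results


def run_intrasubject(per_subject: dict[str, WindowedDataset], k: int = 5,
                     train_cfg: mdl.TrainConfig | None = None,
                     smote: SmoteConfig | None = None, seed: int = 0) -> dict:
    """5-fold within-subject evaluation for every subject.

    Returns per-subject fold results plus the two-stage aggregate
    (fold mean per subject, then mean ± SD over subjects).
    """
    out = {"scheme": "kfold", "subjects": {}}
    for sid, ds in per_subject.items():
        plan = ev.make_intrasubject_folds(len(ds), y=ds.y, k=k, seed=seed)
        out["subjects"][sid] = evaluate_cnn_on_plan(ds, plan, train_cfg, smote)
    out["aggregate"] = _aggregate_intrasubject(out["subjects"])
    return out


def run_loso(dataset: WindowedDataset,
             train_cfg: mdl.TrainConfig | None = None,
             smote: SmoteConfig | None = None) -> dict:
    """Leave-one-subject-out evaluation over a pooled cohort dataset."""
    plan = ev.make_loso_folds(dataset.subject_ids)
    folds = evaluate_cnn_on_plan(dataset, plan, train_cfg, smote)
    out = {"scheme": "loso", "subjects": dict(zip(plan.subjects, folds)),
           "folds": folds}
    out["aggregate"] = {
        metric: ev.aggregate([getattr(f.val, metric) for f in folds])
        for metric in ("accuracy", "f1_functional", "f1_nonfunctional")
    }
    out["aggregate_train"] = {
        metric: ev.aggregate([getattr(f.train, metric) for f in folds])
        for metric in ("accuracy", "f1_functional", "f1_nonfunctional")
    }
    return out


def _aggregate_intrasubject(subjects: dict) -> dict:
    agg = {}
    for split in ("train", "val"):
        for metric in ("accuracy", "f1_functional", "f1_nonfunctional"):
            per_subject = [
                [getattr(getattr(f, split), metric) for f in folds]
                for folds in subjects.values()
            ]
            key = metric if split == "val" else f"train_{metric}"
            agg[key] = ev.aggregate(per_subject, level="subject")
    return agg


# ------------------------------------------------------------------ reports

def report_to_dict(result: dict) -> dict:
    """JSON-serialisable view of a run_intrasubject / run_loso result."""
    def fold_dict(f: FoldResult) -> dict:
        return {"train": f.train.as_dict(), "val": f.val.as_dict(),
                "epochs_run": len(f.history["loss"]),
                "best_epoch": f.history.get("best_epoch"),
                "guards": f.guards}

    out = {"scheme": result["scheme"]}
    out["subjects"] = {
        sid: [fold_dict(f) for f in (folds if isinstance(folds, list) else [folds])]
        for sid, folds in result["subjects"].items()
    }
    for key in ("aggregate", "aggregate_train"):
        if key in result:
            out[key] = {m: {"mean": v[0], "std": v[1]}
                        for m, v in result[key].items()}
    return out


def write_report(result: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(result), fh, indent=2)


# ------------------------------------------------------------- persistence

def save_dataset_h5(path, dataset: WindowedDataset,
                    scaler: RobustWindowScaler | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=dataset.windows)
        f.create_dataset("y", data=dataset.y)
        f.create_dataset("subject_ids",
                         data=np.asarray(dataset.subject_ids, dtype="S"))
        f.attrs["variant"] = dataset.variant
        if scaler is not None:
            f.create_dataset("scaler/median", data=scaler.center_)
            f.create_dataset("scaler/iqr", data=scaler.scale_)


def load_dataset_h5(path):
    import h5py

    with h5py.File(path, "r") as f:
        ds = WindowedDataset(
            windows=f["windows"][...],
            y=f["y"][...],
            subject_ids=f["subject_ids"][...].astype(str),
            variant=str(f.attrs["variant"]),
        )
        scaler = None
        if "scaler" in f:
            scaler = RobustWindowScaler()
            scaler.center_ = f["scaler/median"][...]
            scaler.scale_ = f["scaler/iqr"][...]
            scaler.n_channels_ = ds.n_channels
    return ds, scaler
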