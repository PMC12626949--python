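"""Reading, writing and synchronising wrist-accelerometer recordings.

Accelerometer CSVs use the dialect ``timestamp,x,y,z`` — timestamps in
seconds (float, strictly increasing), acceleration in units of g (the
raw signal includes gravity; no gravity compensation is applied anywhere
in this package).  Video annotations use ``frame,annotator,limb,label``
with labels ``functional`` / ``non-functional`` / ``unknown``.

Sensor and video clocks are aligned through a calibration prelude: the
sensor is oscillated rapidly along its z axis before being strapped on,
producing five distinct peaks in the z channel whose reversal points are
also visible on video.  :func:`detect_sync_peaks` locates the sensor-side
peaks; :func:`align_clocks` fits a linear (offset + drift) map from video
time to sensor time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

# Per-sample label codes used throughout the package.
FUNCTIONAL = 1
NONFUNCTIONAL = 0
UNKNOWN = -1

LABEL_NAMES = {FUNCTIONAL: "functional", NONFUNCTIONAL: "non-functional", UNKNOWN: "unknown"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}


class SchemaError(ValueError):
    """A file does not match the expected column layout."""


class ParseError(ValueError):
    """A file matched the schema but violated a data invariant."""


class SyncError(RuntimeError):
    """Sync-peak detection found the wrong number of calibration peaks."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(
            f"sync failure: found {found} calibration peak(s), expected {expected}"
        )


@dataclass
class RawTrace:
    """One limb's tri-axial acceleration time series.

    Attributes
    ----------
    t : (n,) float array
        Sample timestamps in seconds, strictly increasing.
    a : (n, 3) float array
        Acceleration in g, columns (x, y, z).
    rate_hz : float
        Nominal sampling rate.
    side : {"left", "right"}
    role : {"paretic", "nonparetic"}
    """

    t: np.ndarray
    a: np.ndarray
    rate_hz: float
    side: str = "right"
    role: str = "paretic"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError("a must be (n, 3)")
        if len(self.t) != len(self.a):
            raise ValueError("t and a length mismatch")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ParseError("timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AnnotationSet:
    """Per-frame labels from several independent annotators.

    ``tracks[limb]`` is an (n_annotators, n_frames) int8 array of label
    codes (:data:`FUNCTIONAL` / :data:`NONFUNCTIONAL` / :data:`UNKNOWN`).
    """

    frame_rate_hz: float
    tracks: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = set()
        for limb, arr in self.tracks.items():
            arr = np.asarray(arr, dtype=np.int8)
            if arr.ndim != 2:
                raise ValueError(f"track for {limb!r} must be 2-D")
            if arr.shape[0] < 1:
                raise ValueError("need at least one annotator")
            self.tracks[limb] = arr
            lengths.add(arr.shape[1])
        if len(lengths) > 1:
            raise ValueError("annotator tracks differ in length")

    @property
    def n_annotators(self) -> int:
        arr = next(iter(self.tracks.values()))
        return arr.shape[0]


@dataclass
class ClockMap:
    """Linear map from video time to sensor time: t_sensor = offset_s + scale * t_video."""

    offset_s: float
    scale: float = 1.0
    residual_rms: float = 0.0

    def __post_init__(self):
        if not (0.9 < self.scale < 1.1):
            raise ValueError(f"clock drift scale {self.scale} outside (0.9, 1.1)")

    def video_to_sensor(self, t_video):
        return self.offset_s + self.scale * np.asarray(t_video, dtype=float)

    def sensor_to_video(self, t_sensor):
        return (np.asarray(t_sensor, dtype=float) - self.offset_s) / self.scale


def read_accel_csv(path, side: str = "right", role: str = "paretic",
                   rate_hz: float | None = None) -> RawTrace:
    """Read an accelerometer CSV (``timestamp,x,y,z``) into a :class:`RawTrace`.

    Malformed rows (non-numeric or missing fields) are dropped, counted
    and logged.  Non-monotone timestamps raise :class:`ParseError`;
    missing columns raise :class:`SchemaError`.  When ``rate_hz`` is not
    given it is estimated from the median timestamp step.
    """
    df = pd.read_csv(path)
    required = ["timestamp", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = df[required].apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d malformed row(s)", path, int(bad.sum()))
        df = df[~bad]
    t = df["timestamp"].to_numpy(float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ParseError(f"{path}: timestamps not strictly increasing")
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 30.0
        rate_hz = float(round(rate_hz))
    return RawTrace(t=t, a=df[["x", "y", "z"]].to_numpy(float), rate_hz=rate_hz,
                    side=side, role=role)


def write_accel_csv(path, trace: RawTrace) -> None:
    """Write a trace in the same dialect :func:`read_accel_csv` expects."""
    df = pd.DataFrame({"timestamp": trace.t, "x": trace.a[:, 0],
                       "y": trace.a[:, 1], "z": trace.a[:, 2]})
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotation_csv(path, frame_rate_hz: float = 30.0) -> AnnotationSet:
    """Read an annotation CSV (``frame,annotator,limb,label``)."""
    df = pd.read_csv(path)
    required = ["frame", "annotator", "limb", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    tracks = {}
    for limb, sub in df.groupby("limb"):
        annotators = sorted(sub["annotator"].unique())
        n_frames = int(sub["frame"].max()) + 1
        arr = np.full((len(annotators), n_frames), UNKNOWN, dtype=np.int8)
        for ai, ann in enumerate(annotators):
            rows = sub[sub["annotator"] == ann]
            arr[ai, rows["frame"].to_numpy(int)] = [
                LABEL_CODES[s] for s in rows["label"]
            ]
        tracks[limb] = arr
    return AnnotationSet(frame_rate_hz=frame_rate_hz, tracks=tracks)


def write_annotation_csv(path, ann: AnnotationSet) -> None:
    rows = []
    for limb in sorted(ann.tracks):
        arr = ann.tracks[limb]
        for ai in range(arr.shape[0]):
            for fi in range(arr.shape[1]):
                rows.append((fi, ai, limb, LABEL_NAMES[int(arr[ai, fi])]))
    pd.DataFrame(rows, columns=["frame", "annotator", "limb", "label"]).to_csv(
        path, index=False)


def detect_sync_peaks(trace: RawTrace, axis: int = 2, expected: int = 5,
                      min_separation_s: float = 0.1,
                      prominence_frac: float = 0.5,
                      min_amplitude_g: float = 0.1) -> np.ndarray:
    """Locate the calibration-prelude peaks on one axis (default z).

    Peaks are local maxima of ``|a − median(a)|`` with prominence at least
    ``prominence_frac`` of the maximum deviation and at least
    ``min_separation_s`` apart.  Exactly ``expected`` peaks must be found,
    otherwise :class:`SyncError` reports the count found.

    Using the deviation from the median makes the detector invariant to a
    constant gravity offset on the axis.
    """
    sig = trace.a[:, axis]
    dev = np.abs(sig - np.median(sig))
    peak_dev = float(dev.max(initial=0.0))
    if peak_dev < min_amplitude_g:
        raise SyncError(found=0, expected=expected)
    distance = max(1, int(round(min_separation_s * trace.rate_hz)))
    idx, _ = find_peaks(dev, prominence=prominence_frac * peak_dev,
                        distance=distance)
    if len(idx) != expected:
        raise SyncError(found=len(idx), expected=expected)
    return trace.t[idx]


def align_clocks(sensor_peaks, video_peaks) -> ClockMap:
    """Least-squares linear map from video peak times to sensor peak times.

    With identical lists the result is the identity map (offset 0, scale 1).
    """
    s = np.asarray(sensor_peaks, dtype=float)
    v = np.asarray(video_peaks, dtype=float)
    if len(s) != len(v):
        raise ValueError("peak lists differ in length")
    if len(s) < 2:
        raise ValueError("need at least 2 peaks to align clocks")
    scale, offset = np.polyfit(v, s, 1)
    resid = s - (offset + scale * v)
    return ClockMap(offset_s=float(offset), scale=float(scale),
                    residual_rms=float(np.sqrt(np.mean(resid ** 2))))
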