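"""Synthetic wrist-accelerometry cohorts with known ground truth.

Real recordings of this kind contain three ingredients: gravity (the
raw signal is not gravity-compensated, so a resting wrist reads +1 g on
whichever axis points down), functional arm use (reaching, grasping,
gesturing — short smooth bursts that re-orient the wrist and add
transient movement acceleration), and non-functional motion (gait-
associated arm swing, a narrow-band oscillation, or plain stillness).
The generator emulates exactly that structure:

* a **sync prelude** of five sharp z-axis half-cycle pulses (2 Hz, 2 g)
  before "attachment", giving five distinct peaks for clock alignment;
* **functional bursts** scheduled as an alternating renewal process whose
  mean burst/gap durations realise a requested functional-use fraction;
  each burst smoothly tilts the gravity vector (up to ~60°) and adds a
  smooth minimum-jerk-like acceleration pulse on the horizontal axes;
* **non-functional segments** that are either rest (gravity + noise) or
  gait-like sinusoidal arm swing;
* **annotator tracks** that equal the ground truth except near label
  transitions, where each annotator's perceived boundary is jittered and
  occasionally marked unknown — disagreement concentrated at
  transitions, as observed with human video annotators.

Cohorts are written to disk in the same CSV dialect ``sensor_io`` reads,
with a YAML manifest, and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .preprocess import LabelTrack
from .sensor_io import (
    FUNCTIONAL,
    NONFUNCTIONAL,
    UNKNOWN,
    AnnotationSet,
    RawTrace,
    write_accel_csv,
    write_annotation_csv,
)

SUPPORTED_RATES = (30, 50, 200)

PRELUDE_FREQ_HZ = 2.0
PRELUDE_AMPLITUDE_G = 2.0
PRELUDE_PEAKS = 5
# five half-cycle pulses -> five |z - median| peaks 0.25 s apart
PRELUDE_S = PRELUDE_PEAKS / (2 * PRELUDE_FREQ_HZ)
# quiet interval after the prelude while the sensor is strapped on
DONNING_S = 3.0


@dataclass
class MovementProfile:
    """Statistical description of one subject-arm's movement content.

    Parameters
    ----------
    functional_fraction : float in [0, 1]
        Target fraction of (non-prelude) time spent in functional use.
    burst_rate : float
        Informational functional-burst rate per minute implied by the
        fraction and duration; recomputed property.
    burst_duration_s : float
        Mean duration of one functional burst.
    gait_amplitude_g : float
        Amplitude of the gait-like arm-swing oscillation.
    noise_sd_g : float
        White accelerometer noise standard deviation.
    gravity_axis : {"x", "y", "z"}
        Axis reading +1 g at rest (sensor mounting).
    """

    functional_fraction: float = 0.3
    burst_duration_s: float = 4.0
    gait_amplitude_g: float = 0.25
    noise_sd_g: float = 0.02
    gravity_axis: str = "z"
    tilt_max_deg: float = 60.0
    movement_amp_g: float = 0.6
    gait_freq_hz: float = 1.0
    # broadband acceleration texture present whenever the arm moves
    motion_jitter_g: float = 0.08

    def __post_init__(self):
        if not 0.0 <= self.functional_fraction <= 1.0:
            raise ValueError("functional_fraction must be in [0, 1]")
        if self.burst_duration_s <= 0:
            raise ValueError("burst_duration_s must be positive")
        for name in ("gait_amplitude_g", "noise_sd_g", "movement_amp_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.gravity_axis not in ("x", "y", "z"):
            raise ValueError("gravity_axis must be one of x, y, z")

    @property
    def burst_rate(self) -> float:
        """Implied functional bursts per minute."""
        if self.functional_fraction == 0:
            return 0.0
        return 60.0 * self.functional_fraction / self.burst_duration_s


@dataclass
class CohortConfig:
    """Layout of a synthetic multi-subject recording cohort."""

    n_subjects: int = 8
    rates_hz: tuple = (30, 50, 200)
    session_minutes: float = 10.0
    annotators: int = 3
    transition_jitter_s: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.session_minutes <= 0:
            raise ValueError("session_minutes must be positive")
        if self.annotators < 1:
            raise ValueError("need at least one annotator")
        for r in self.rates_hz:
            if r not in SUPPORTED_RATES:
                raise ValueError(f"unsupported rate {r}; choose from {SUPPORTED_RATES}")


def _axis_index(axis: str) -> int:
    return {"x": 0, "y": 1, "z": 2}[axis]


def _schedule_segments(n_active: int, rate_hz: float,
                       profile: MovementProfile, rng: np.random.Generator):
    """Alternating functional-burst / non-functional-gap schedule.

    Burst lengths are drawn around ``burst_duration_s`` and gap lengths
    around the mean that realises ``functional_fraction``; by the law of
    large numbers the empirical fraction concentrates on the target for
    sessions of a few minutes or more.
    Returns a list of (start, stop, label, kind) sample-index segments,
    kind in {"rest", "gait", "burst"}.
    """
    f = profile.functional_fraction
    segs = []
    pos = 0
    if f <= 0:
        while pos < n_active:
            length = max(1, int(rng.normal(8.0, 2.0) * rate_hz))
            stop = min(pos + length, n_active)
            kind = "gait" if rng.random() < 0.5 else "rest"
            segs.append((pos, stop, NONFUNCTIONAL, kind))
            pos = stop
        return segs
    gap_mean = profile.burst_duration_s * (1 - f) / f if f < 1 else 0.0
    functional_turn = rng.random() < f
    while pos < n_active:
        if functional_turn:
            dur = max(0.5, rng.normal(profile.burst_duration_s,
                                      0.2 * profile.burst_duration_s))
            stop = min(pos + int(dur * rate_hz), n_active)
            segs.append((pos, stop, FUNCTIONAL, "burst"))
        else:
            dur = max(0.5, rng.normal(gap_mean, 0.25 * gap_mean)) if gap_mean > 0 else 0.5
            stop = min(pos + int(dur * rate_hz), n_active)
            kind = "gait" if rng.random() < 0.5 else "rest"
            segs.append((pos, stop, NONFUNCTIONAL, kind))
        pos = stop
        functional_turn = not functional_turn
    return segs


def _minimum_jerk_pulse(n: int) -> np.ndarray:
    """Smooth bell-shaped acceleration profile of a point-to-point reach.

    Second derivative of the minimum-jerk position polynomial
    10τ³ − 15τ⁴ + 6τ⁵, normalised to unit peak magnitude.
    """
    tau = np.linspace(0.0, 1.0, n)
    acc = 60 * tau - 180 * tau ** 2 + 120 * tau ** 3
    peak = np.abs(acc).max()
    return acc / peak if peak > 0 else acc


def generate_session(profile: MovementProfile, rate_hz: int = 30,
                     minutes: float = 10.0, seed: int = 0,
                     include_prelude: bool = True,
                     return_segments: bool = False):
    """Simulate one limb's session: trace plus ground-truth labels.

    The trace has exactly ``rate_hz × 60 × minutes`` samples.  A sync
    prelude of five z-axis pulses occupies the first
    :data:`PRELUDE_S` seconds (labeled non-functional: the device is
    being oscillated by the experimenter, not used functionally).
    Resting samples read +1 g on the profile's gravity axis.
    """
    if rate_hz not in SUPPORTED_RATES:
        raise ValueError(f"unsupported rate {rate_hz}; choose from {SUPPORTED_RATES}")
    rng = np.random.default_rng(seed)
    n = int(round(rate_hz * 60 * minutes))
    t = np.arange(n) / rate_hz
    a = np.zeros((n, 3))
    labels = np.full(n, NONFUNCTIONAL, dtype=np.int8)
    g_idx = _axis_index(profile.gravity_axis)
    a[:, g_idx] = 1.0

    n_pre = int(round(PRELUDE_S * rate_hz)) if include_prelude else 0
    if n_pre:
        tp = t[:n_pre]
        # five half-cycle pulses -> five sharp |z - median| peaks, 0.25 s apart
        a[:n_pre, 2] += PRELUDE_AMPLITUDE_G * np.abs(
            np.sin(2 * np.pi * PRELUDE_FREQ_HZ * tp))
        # the sensor is strapped on during a quiet donning interval
        n_pre += int(round(DONNING_S * rate_hz))
        n_pre = min(n_pre, n)

    horiz = [i for i in range(3) if i != g_idx]
    segments = _schedule_segments(n - n_pre, rate_hz, profile, rng)
    for start, stop, label, kind in segments:
        s, e = start + n_pre, stop + n_pre
        m = e - s
        if m <= 0:
            continue
        labels[s:e] = label
        if kind == "burst":
            # smooth wrist re-orientation: gravity vector tilts and returns
            theta_max = np.deg2rad(rng.uniform(0.4, 1.0) * profile.tilt_max_deg)
            env = np.sin(np.pi * np.linspace(0, 1, m)) ** 2
            theta = theta_max * env
            tilt_to = horiz[int(rng.integers(2))]
            a[s:e, g_idx] += np.cos(theta) - 1.0
            a[s:e, tilt_to] += np.sin(theta) * (1 if rng.random() < 0.5 else -1)
            # movement acceleration: one or two reach pulses per burst
            amp = profile.movement_amp_g * rng.uniform(0.6, 1.0)
            a[s:e, horiz[0]] += amp * _minimum_jerk_pulse(m)
            a[s:e, horiz[1]] += 0.5 * amp * _minimum_jerk_pulse(m)[::-1]
            if profile.motion_jitter_g > 0:
                a[s:e] += rng.normal(0.0, profile.motion_jitter_g, size=(m, 3))
        elif kind == "gait":
            phase = rng.uniform(0, 2 * np.pi)
            freq = profile.gait_freq_hz * rng.uniform(0.85, 1.15)
            swing = profile.gait_amplitude_g * np.sin(
                2 * np.pi * freq * t[s:e] + phase)
            a[s:e, horiz[0]] += swing
            a[s:e, horiz[1]] += 0.3 * profile.gait_amplitude_g * np.sin(
                4 * np.pi * freq * t[s:e] + phase)
            if profile.motion_jitter_g > 0:
                a[s:e] += rng.normal(
                    0.0, 0.5 * profile.motion_jitter_g, size=(m, 3))
    if profile.noise_sd_g > 0:
        a += rng.normal(0.0, profile.noise_sd_g, size=a.shape)
    trace = RawTrace(t=t, a=a, rate_hz=rate_hz)
    truth = LabelTrack(rate_hz=rate_hz, labels=labels)
    if return_segments:
        # segment indices are relative to the end of the prelude/donning
        shifted = [(s + n_pre, e + n_pre, lab, kind)
                   for s, e, lab, kind in segments]
        return trace, truth, shifted
    return trace, truth


def generate_annotations(truth: LabelTrack, annotators: int = 3,
                         transition_jitter_s: float = 0.3, seed: int = 0,
                         unknown_prob: float = 0.25,
                         limb: str = "paretic") -> AnnotationSet:
    """Emulate independent human annotators of the same ground truth.

    Each annotator reproduces the truth exactly except near class
    boundaries: their perceived transition time is shifted by a uniform
    jitter within ``±transition_jitter_s``, and with probability
    ``unknown_prob`` the samples between the true and perceived boundary
    are marked unknown instead.  With zero jitter every annotator equals
    the truth.
    """
    if annotators < 1:
        raise ValueError("need at least one annotator")
    rng = np.random.default_rng(seed)
    n = len(truth)
    jitter = int(round(transition_jitter_s * truth.rate_hz))
    boundaries = np.flatnonzero(np.diff(truth.labels)) + 1  # index of first sample after change
    tracks = np.tile(truth.labels, (annotators, 1)).astype(np.int8)
    if jitter > 0:
        for ai in range(annotators):
            for b in boundaries:
                shift = int(rng.integers(-jitter, jitter + 1))
                if shift == 0:
                    continue
                lo, hi = (b, min(n, b + shift)) if shift > 0 else (max(0, b + shift), b)
                if rng.random() < unknown_prob:
                    tracks[ai, lo:hi] = UNKNOWN
                else:
                    # perceived boundary moved: that side's label extends
                    src = truth.labels[b - 1] if shift > 0 else truth.labels[min(b, n - 1)]
                    tracks[ai, lo:hi] = src
    return AnnotationSet(frame_rate_hz=truth.rate_hz, tracks={limb: tracks})


def default_cohort_profiles(n_subjects: int, seed: int = 0,
                            heterogeneous: bool = False,
                            noise_sd_g: float = 0.02):
    """Per-subject (paretic, non-paretic) movement profiles.

    The paretic arm gets a lower functional-use fraction than the
    non-paretic arm, mirroring the reduced affected-arm use typical of
    stroke cohorts.  With ``heterogeneous=True`` subjects additionally
    differ in sensor mounting (gravity axis), gait frequency and movement
    amplitude, which widens the across-subject generalisation gap.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        frac_p = float(rng.uniform(0.15, 0.45))
        frac_np = float(np.clip(frac_p + rng.uniform(0.15, 0.35), 0, 0.6))
        kw = dict(noise_sd_g=noise_sd_g)
        if heterogeneous:
            kw.update(
                gravity_axis=("x", "y", "z")[int(rng.integers(3))],
                gait_freq_hz=float(rng.uniform(0.6, 1.6)),
                movement_amp_g=float(rng.uniform(0.2, 0.9)),
                gait_amplitude_g=float(rng.uniform(0.1, 0.45)),
                burst_duration_s=float(rng.uniform(2.0, 7.0)),
            )
        profiles.append((MovementProfile(functional_fraction=frac_p, **kw),
                         MovementProfile(functional_fraction=frac_np, **kw)))
    return profiles


@dataclass
class SyntheticSubject:
    """In-memory session for one subject: both arms plus annotations."""

    subject_id: str
    rate_hz: int
    paretic_side: str
    traces: dict          # {"paretic": RawTrace, "nonparetic": RawTrace}
    truths: dict          # {"paretic": LabelTrack, ...} at the native rate
    annotations: AnnotationSet


def generate_subject(subject_id: str, profiles, rate_hz: int, minutes: float,
                     annotators: int, transition_jitter_s: float,
                     seed: int, paretic_side: str = "left") -> SyntheticSubject:
    prof_p, prof_np = profiles
    traces, truths, tracks = {}, {}, {}
    for k, (role, prof) in enumerate([("paretic", prof_p), ("nonparetic", prof_np)]):
        trace, truth = generate_session(prof, rate_hz, minutes,
                                        seed=(seed * 4 + k) % 2_147_483_647)
        trace.role = role
        trace.side = paretic_side if role == "paretic" else \
            ("right" if paretic_side == "left" else "left")
        ann = generate_annotations(truth, annotators, transition_jitter_s,
                                   seed=(seed * 4 + 2 + k) % 2_147_483_647,
                                   limb=role)
        traces[role], truths[role] = trace, truth
        tracks[role] = ann.tracks[role]
    annotations = AnnotationSet(frame_rate_hz=rate_hz, tracks=tracks)
    return SyntheticSubject(subject_id=subject_id, rate_hz=rate_hz,
                            paretic_side=paretic_side, traces=traces,
                            truths=truths, annotations=annotations)


def generate_cohort(config: CohortConfig, profiles, out_dir=None):
    """Generate a whole cohort; optionally write it to ``out_dir``.

    ``profiles`` is a list of (paretic, nonparetic)
    :class:`MovementProfile` pairs, one per subject.  Output layout::

        out_dir/manifest.yaml
        out_dir/<subject>/paretic.csv, nonparetic.csv, annotations.csv

    The manifest records each subject's rate, paretic side and the
    empirical functional fraction recounted from the generated labels.
    Deterministic (byte-identical files) for a fixed seed.
    """
    if len(profiles) != config.n_subjects:
        raise ValueError("need one profile pair per subject")
    subjects = []
    manifest = {"seed": config.seed, "annotators": config.annotators,
                "session_minutes": config.session_minutes, "subjects": {}}
    seen = set()
    for i in range(config.n_subjects):
        sid = f"s{i:02d}"
        if sid in seen:
            raise ValueError(f"duplicate subject id {sid}")
        seen.add(sid)
        rate = int(config.rates_hz[i % len(config.rates_hz)])
        side = "left" if i % 2 == 0 else "right"
        subj = generate_subject(sid, profiles[i], rate, config.session_minutes,
                                config.annotators, config.transition_jitter_s,
                                seed=(config.seed * 1000 + i) % 2_147_483_647,
                                paretic_side=side)
        subjects.append(subj)
        manifest["subjects"][sid] = {
            "rate_hz": rate,
            "paretic_side": side,
            "functional_fraction_paretic": round(
                subj.truths["paretic"].functional_fraction(), 4),
            "functional_fraction_nonparetic": round(
                subj.truths["nonparetic"].functional_fraction(), 4),
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for subj in subjects:
            d = out_dir / subj.subject_id
            d.mkdir(exist_ok=True)
            for role in ("paretic", "nonparetic"):
                write_accel_csv(d / f"{role}.csv", subj.traces[role])
            write_annotation_csv(d / "annotations.csv", subj.annotations)
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return subjects, manifest


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(manifest, sort_keys=True).encode()).hexdigest()
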