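# Methods

This note documents the models, procedures and design choices behind
`armuse`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic experiments do and do
not demonstrate.

## Problem setting

A stroke survivor wears one tri-axial accelerometer on each wrist while
performing everyday activities; simultaneous video is annotated
per frame and per limb as *functional* (purposeful arm use),
*non-functional* (gait-related swing, whole-body motion, stillness) or
*unknown* (arm out of view / ambiguous). The task is a binary,
per-window classification of the accelerometry: is this 2-s stretch of
movement functional? Raw acceleration is expressed in units of g and
includes gravity; no gravity compensation is applied, so posture
(orientation of the gravity vector in the sensor frame) is part of the
signal the classifier may exploit.

## Preprocessing

1. **Resampling.** All recordings are brought to 30 Hz. Rates above
   30 Hz (50, 200) are decimated with `scipy.signal.resample_poly`,
   whose polyphase FIR low-passes at the output Nyquist (15 Hz) before
   decimation. 30 Hz input passes through untouched. Rates below 30 Hz
   are rejected rather than up-sampled.
2. **Axis harmonisation.** Left-wrist sensors are mirrored relative to
   right-wrist sensors; negating one axis (configurable, default x)
   makes both arms anatomically consistent. The transform is an
   involution and a no-op for right-side traces.
3. **Clock alignment.** Before attachment the sensor is oscillated
   rapidly along z, producing five sharp peaks. The detector finds local
   maxima of |z − median(z)| with prominence ≥ 50% of the maximum
   deviation and ≥ 0.1 s separation; using the deviation from the median
   makes it invariant to the constant gravity offset. Finding any number
   of peaks other than the expected five is a hard error (reporting the
   count found) rather than a silent misalignment. Video-side reversal
   times are taken as given; a least-squares linear map (offset + drift
   scale) aligns video time to sensor time, reducing to the identity
   when both peak lists coincide. Drift scales outside (0.9, 1.1) are
   rejected as physically implausible.
4. **Labels.** Per-frame annotator votes are collapsed by *strict
   majority*; frames without a strict majority become unknown. Labels
   are transferred to the 30 Hz timeline by mapping each sensor
   timestamp into video time and taking the covering frame's label;
   samples outside the annotated span, and the pre-attachment prelude,
   are unknown.
5. **Windowing.** Unknown samples are removed first; each maximal
   contiguous remaining run is tiled with non-overlapping 60-sample
   (2-s) windows from its start, dropping trailing remainders. A
   window's label is the strict majority of its 60 sample labels; the
   rare exactly-tied windows (< 2% on synthetic cohorts) are dropped as
   ambiguous rather than guessed. Consequently no unknown label ever
   reaches a dataset, and the combined-arms variant (which removes
   samples where *either* arm is unknown before windowing) can never
   contain more windows than the paretic variant.
6. **Scaling.** Per channel, `X_scaled = (X − Q2)/IQR` with quantiles
   pooled over all training windows and time steps of the current fold
   (train-only fitting avoids leakage into validation data). A zero-IQR
   channel is divided by 1 with a warning, mapping constant channels to
   zero.

Three dataset variants are produced: paretic arm (3 channels, paretic
labels), non-paretic arm, and combined arms (6 channels, paretic
labels).

## Classifier

Input windows are (60, C, 1) with C ∈ {3, 6}. The network is
feature extraction → aggregation → classification: two 3×3 stride-1
convolution blocks (16 then 32 filters, each with batch normalisation,
ReLU and 20% dropout), a flatten, two 64-unit ReLU dense layers with L2
kernel penalty λ = 1e-3 and 30% dropout, and a single sigmoid output
giving P(functional). Convolutions use "same" zero padding on both the
time and channel axes — with valid padding a second 3×3 convolution
would annihilate a 3-channel axis — and there are no pooling layers.
For C = 3 the model has 377,825 trainable parameters (plus 96
non-trainable batch-norm statistics).

Training: Adam (initial LR 1e-3), binary cross-entropy, batch size 64,
at most 700 epochs. Two callbacks with the usual Keras-style semantics:
reduce-LR-on-plateau watches the *validation loss* (factor 0.1, patience
10, min improvement 1e-4) and early stopping watches the *validation
accuracy* (patience 20) and restores the weights of the best validation
epoch, so the reported validation metric equals the maximum over the
history. Batch norm uses batch statistics during training (running
statistics, momentum 0.9, at inference); dropout is inactive at
inference, so prediction is deterministic for fixed weights.

The engine is pure NumPy (im2col convolutions, analytic backprop
verified against finite differences in the test suite), float32, driven
by a single seeded `numpy.random.Generator`; for a fixed seed two runs
produce identical histories. The positive class is *functional* — the
clinically salient detection target; `classify` maps p ≥ 0.5 → 1.

## Class imbalance

Severely impaired subjects may show 3–8% functional use, which starves
the minority class. SMOTE synthesises minority windows by interpolating
between a random minority sample and one of its k = 5 nearest minority
neighbours (Euclidean distance in the flattened, *scaled* window space;
scaling first makes distances commensurable across channels):
`x_new = x_i + u (x_nn − x_i)`, `u ~ U(0,1)`. Rebalancing targets a
minority/majority ratio of 0.5 — i.e. exactly
`ceil(0.5·n_maj) − n_min` synthetics, leaving the minority at 33.3% of
the training set — and is applied to training folds only; synthetic
samples are tagged so leakage checks can find them. Synthesis
provenance (parent, neighbour, u) is recorded, letting tests verify the
geometry against an O(n²) brute-force neighbour ranking.

## Evaluation

*Intrasubject*: each subject's windows are split into 5 folds,
stratified by class when both classes have ≥ 5 windows (plain shuffled
folds otherwise — tiny minorities cannot be stratified); metrics are
averaged over folds per subject, then mean ± SD across subjects.
*Intersubject*: leave-one-subject-out; one fold per subject, trained on
all others, aggregated as mean ± SD over held-out subjects. All SDs use
the n−1 denominator. Train/test subject disjointness is asserted on
every LOSO fold, and each fold's report carries an instrumentation
record showing what the scaler and SMOTE were fitted on.

Metrics are accuracy and per-class F1, stored with raw confusion counts
(functional = positive). When a class is absent from both truth and
prediction its F1 is reported as 0 with a warning — the conservative
convention for near-zero-use subjects. Paired train-vs-validation
comparisons use a two-sided paired t-test (p is NaN when the
differences have zero variance) and Cohen's d with the pooled-SD
denominator, `d = mean(diff)/sqrt((sd_tr² + sd_val²)/2)`, with 95% CI
`d ± 1.96·se`, `se = sqrt(1/n + d²/2n)·sqrt(2(1−r))` (r = pairing
correlation); the alternative `d_z = mean(diff)/sd(diff)` convention is
reported alongside, since which convention a given study used is often
unstated.

The random-forest baseline (500 trees, √p features per split, fixed
seed) consumes 21 handcrafted time-domain features per arm — mean, SD,
min, max, RMS per channel; signal magnitude area; the three pairwise
channel correlations; mean and SD of |a| — plus the 9 cross-arm
correlations for the combined variant, and is evaluated on the *same*
split plans as the CNN.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not validated biomechanics:

* **Sync prelude** — five half-cycle 2 Hz pulses of 2 g on z (five
  |z−median| peaks 0.25 s apart), followed by a 3-s quiet "donning"
  interval while the sensor is strapped on.
* **Functional bursts** — an alternating renewal schedule whose mean
  burst (default 4 s) and gap durations realise a requested
  functional-use fraction (empirically within ±0.05 for ≥ 10-min
  sessions); each burst smoothly tilts the gravity vector by up to
  ~60° (sin² envelope) and adds a minimum-jerk acceleration pulse
  (second derivative of 10τ³−15τ⁴+6τ⁵) on the horizontal axes.
* **Non-functional segments** — rest (gravity + white noise, magnitude
  1 g ± noise SD) or gait-like arm swing (≈1 Hz sinusoid, default
  0.25 g, with a second harmonic).
* **Motion texture** — any moving segment carries broadband
  acceleration jitter (default 0.08 g SD for bursts, half for gait),
  reflecting that real limb movement is never spectrally clean; this is
  what makes rest/motion separable by a moving-SD threshold (≥ 99% at
  noise ≤ 0.02 g, asserted in the tests) and keeps burst edges
  detectable.
* **Annotators** — each annotator equals the ground truth except near
  label transitions, where the perceived boundary shifts by a uniform
  jitter (default ±0.3 s) and is occasionally marked unknown — mimicking
  the observation that human annotator disagreement concentrates at
  transition timing. Unknown labels enter only through annotation, not
  ground truth.
* **Cohorts** — paretic arms get lower functional fractions than
  non-paretic arms (0.15–0.45 vs +0.15–0.35, capped at 0.6), exercising
  the imbalance path; sampling rates cycle over 30/50/200 Hz;
  `heterogeneous=True` additionally varies sensor mounting (gravity
  axis), gait frequency, movement amplitude and burst duration across
  subjects, which is what makes across-subject (LOSO) generalisation
  genuinely harder than within-subject evaluation.

Everything is bit-reproducible for a fixed seed, including the on-disk
CSV/YAML cohort files.

**What passing tests show — and don't.** The synthetic classes are
separable by construction, so high accuracy demonstrates that the
pipeline is *correct* (no leakage, labels aligned, model able to learn
the class structure), not that real stroke accelerometry would be
classified this accurately. Real data adds soft-tissue artifacts,
idiosyncratic compensatory movements, annotation errors beyond boundary
jitter, and overlapping class spectra, none of which are modeled.

## Problem sizes and run configuration

The acceptance script and end-to-end tests use an 8-subject,
10-min-per-subject separable cohort (noise SD 0.02 g, mixed
30/50/200 Hz rates) for the learnability checks, a 5-subject, 5-min
heterogeneous cohort for the generalisation-gap check, and a single
10-min subject at 5% functional use (weaker, noisier bursts, as in
severe impairment) for the imbalance checks. These runs cap training at
120 epochs — on these cohorts early stopping consistently triggers near
epoch 25–60, well inside the cap, so the 700-epoch schedule is
unconstrained in practice.

## Numerical choices and degenerate inputs

* Window-label ties → window dropped (never guessed).
* Zero-IQR channels → divide by 1, warn.
* F1 with no positives anywhere → 0, warn; SD of a single value → 0,
  warn.
* Sync detection on a flat trace → failure with count 0 (an absolute
  0.1 g floor prevents declaring "peaks" in noise).
* Single-class training folds raise immediately and point the caller at
  the imbalance module.
* Weight init is Glorot uniform; all randomness (init, shuffling,
  dropout, SMOTE, schedules) flows from explicit integer seeds.

## Known limitations

* The NumPy training loop is single-threaded and unsuited to cohorts
  orders of magnitude larger than the synthetic ones.
* The generator's spectral content is a design choice; no published
  characterisation of functional vs non-functional wrist spectra was
  available to fit it to.
* Automatic video-side sync-peak marking is out of scope; video peak
  times are inputs.
* Gyroscope channels, gravity compensation, attribution methods and
  alternative sequence models (LSTM/transformer) are deliberately not
  implemented.
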