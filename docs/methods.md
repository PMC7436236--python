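# Methods

`gaitforce` estimates the vertical ground reaction force (vGRF) during
walking, sample by sample, from a single 6-axis inertial measurement unit
(IMU) worn on the foot, shank, distal thigh or proximal thigh.  The package
has two halves: a synthetic treadmill-gait generator that produces paired
IMU + reference-force recordings with known ground truth, and the
estimation pipeline evaluated on those recordings under within-subject and
across-subject protocols.

## Estimation pipeline

1. **Preprocessing.**  Each IMU channel passes a 5-sample running median
   (edge replication at the boundaries), suppressing isolated spikes
   without smearing the heel-strike transient.
2. **Windowed features.**  A centred 110 ms window (11 samples at 100 Hz,
   stride 1) slides over each channel; 13 time-domain feature families —
   RMS, sum of absolute values, mean absolute deviation, variance, waveform
   length, slope-sign changes, simple square integral, mean absolute db7
   wavelet detail, difference absolute standard deviation, average
   amplitude change, log detector, and linear and parabolic least-squares
   fit coefficients — yield 16 scalars per channel, 96 per location.
   Centred windows avoid a systematic half-window lag in the estimate;
   edge-replicated boundaries keep row *i* aligned with raw sample *i*.
3. **Normalization.**  Features are min-max scaled to [0, 1] with bounds
   computed from training rows only; test values outside the training range
   are clipped, and constant columns map to 0.  Fitting bounds on training
   data alone is the leakage-free choice.
4. **Regression.**  A bagged ensemble of 50 regression trees with
   5-sample minimum leaves maps each normalized feature row to the force at
   the window centre (in body weights, BW).  Splits maximize variance
   reduction over ceil(96/3) = 32 randomly drawn candidate features per
   node; the ensemble output is the mean over trees (the regression analogue
   of vote aggregation).  The default engine wraps
   `sklearn.ensemble.RandomForestRegressor` with exactly these
   hyperparameters and exports its trees into the package's own flat
   arrays; a bespoke NumPy implementation of the same split and stopping
   rules ships alongside as the reference, and a test asserts the two reach
   the same synthetic-task NRMSE within 20% relative.
5. **Post-processing.**  The predicted force is low-pass filtered at 10 Hz
   (4th-order Butterworth, zero-phase forward-backward pass, so peak
   timings are not shifted); the high-frequency component is defined as the
   exact complement `y - lowpass(y)`, making the decomposition additive by
   construction.
6. **Gait events.**  Stances are maximal runs with force ≥ 20 N (converted
   to BW via the subject's mass, ≈ 0.0283 BW at 72 kg); runs shorter than
   100 ms and the possibly-truncated first and last runs are discarded.
   The passive peak (PP) is the largest interior local maximum in the first
   half of a stance, the active peak (AP) in the second half; ties go to
   the earlier index, and a half without an interior maximum falls back to
   its largest sample (flagged).  Peaks of the estimated signal are
   searched within the *reference* stance windows so every estimated peak
   has an unambiguous partner; errors and delays are reference − estimate
   (delay in percent of stance duration, so a positive delay means the
   estimated peak fired early).

## Evaluation protocols and metrics

* **Intra-participant:** per subject, the first half of every speed trial
  (in time order, no shuffling; windows assigned by centre sample, odd
  lengths floor to the training side) trains the model, the second half
  tests it.
* **Inter-participant:** leave-one-subject-out (LOSO) — train on the eight
  other subjects' full trials, test on the held-out subject; every subject
  is held out once.

Per subject, R (Pearson), RMSE (BW) and NRMSE (100·RMSE / reference range,
%) are pooled over all test samples across speeds ("whole course") and
additionally recomputed per speed; reports give mean (SD) across subjects.
Cells with zero reference range or variance are flagged and excluded.
Location and speed effects are tested with a two-way fixed-effects ANOVA
with interaction on the balanced subjects-as-replicates design (Type-I sums
of squares, which coincide with the textbook decomposition there), followed
by Tukey HSD on a factor's marginal means using the ANOVA error term
(studentized-range reference distribution), at alpha = 0.05.

## Synthetic cohort

No public recording accompanies the protocol this package emulates, so the
generator *defines* the study conditions: 9 subjects × 5 belt speeds (0.4,
0.7, 1.0, 1.3, 1.6 m/s) × 60 s at 100 Hz.  Its functional forms are chosen
so that the assumptions the pipeline relies on hold by construction:

* **Stance force.**  Two Gaussian bumps (centres 25% / 75% of stance,
  width 0.11) on a 0.55·sin(π·τ) mid-stance support term; bump amplitudes
  1.05 + 0.12·speed (passive) and 1.02 + 0.10·speed (active), scaled by
  per-subject gains.  The line through the raw curve's endpoint values is
  subtracted before clipping at zero so the force vanishes exactly at
  initial contact and toe-off.  Peak force stays in 0.9–1.6 BW and grows
  with speed.
* **Heel-strike transient.**  An exponentially damped 15 Hz sinusoid
  (80 ms support, 20 ms decay constant, amplitude 8% of the passive-peak
  bump) adds the >10 Hz content seen at impact.
* **Cadence.**  Cycle time T(s) = clip(1.9 − 0.5·s, 0.8, 1.8) s, scaled by
  a per-subject factor (SD 3%); stance occupies a per-subject fraction of
  the cycle (mean 0.62, SD 0.02, truncated to [0.5, 0.7]).
* **IMU channels.**  Deterministic smooth functions of the gait-cycle
  phase — gravity projected through a segment-sway angle, speed-scaled
  sagittal angular-velocity sinusoids with per-location amplitudes
  (250/150/80/60 deg/s for foot/shank/distal/proximal thigh) — plus a term
  proportional to the local force (coupling 0.35/0.25/0.18/0.12 of g) and
  the impact transient attenuated up the limb.  Channel triads are rotated
  by a per-subject mounting misalignment (per-axis SD 3°) and then
  corrupted with white noise (defaults 0.05 m/s² accelerometer, 0.5 deg/s
  gyroscope).  Because every channel is a function of phase and the force
  is too, an 11-sample noise-free window determines the centre force
  exactly — the regression problem is well-posed, which a lookup-table test
  verifies.
* **Population.**  Body mass ~ N(72, 9²) kg truncated at 45 kg; passive /
  active peak gains ~ N(1, 0.05²); impact gain ~ N(1, 0.10²).  The
  reference force channel is always noise-free (it stands in for the force
  plate); only the IMU carries noise.

What the generator does **not** emulate: soft-tissue artefact, sensor
drift and bias instability, double-support force sharing between limbs,
step-to-step variability within a trial (cycles are exactly periodic up to
sensor noise), asymmetry, or non-sagittal motion beyond fixed phase
offsets.  Passing tests therefore demonstrate that the pipeline recovers a
force signal that is genuinely encoded in the IMU stream under realistic
noise and between-subject variation — not that it reaches any particular
accuracy on real walking data.

## Numerical choices and edge cases

* Zero-phase filtering needs > 12 samples; shorter signals raise.
* The log-detector guard is ε = 1e−12 (the formula is undefined at zero).
* Slope-sign changes use the strict product rule (no amplitude deadband).
* The db7 single-level DWT uses symmetric padding (the db7 filter is longer
  than the 11-sample window, so padding is unavoidable; the mean absolute
  detail coefficient is the feature).
* Tree splits fall between distinct sorted feature values with both
  children ≥ the minimum leaf size; targets with zero variance stop
  growth.  Model JSON stores plain arrays and round-trips exactly.
* Stance detection guarantees the threshold crossing brackets every kept
  stance: y[start−1] < threshold ≤ y[start].

A known accuracy floor: with sensor noise at zero the pipeline still shows
~0.3–0.9% NRMSE, from two sources — the estimate is low-pass filtered at
10 Hz while the reference keeps its >10 Hz transient, and 5-sample leaves
average a few adjacent gait phases whenever a phase repeats fewer than
about five times in training.  Both are properties of the published
pipeline settings, not defects of the fit.

## Problem sizes

Trial duration is the scale knob (cohort structure is never reduced): the
packaged evaluation runs use 30 s trials for the intra-participant
protocol and 10 s trials for LOSO (nine 8-subject training folds of ~40k
rows each); the test suite uses 20 s / 8 s, and the analysis drivers 10 s /
6 s.  Accuracy is insensitive to these choices well within the reported
margins, since metrics are per-sample and each trial still contains many
gait cycles.

## Limitations

Walking only (no running), vertical component only, fixed 100 Hz rate, and
a synthetic cohort whose difficulty is set by the variability parameters
above; the inter-participant gap measured here (a few percent NRMSE) will
underestimate the gap on real populations with larger anatomical and
behavioural variation.
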