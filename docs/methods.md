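# Methods

This package implements an offline terrain-prediction pipeline for
transtibial amputee gait: given one stride of multichannel residual-limb
signals, predict whether the upcoming footfall lands on an everting
(−15°), flush (0°) or inverting (+15°) cross-slope. The pipeline is
exercised end-to-end on a synthetic stride generator, so every stage is
testable without human-subject recordings.

## Signal inventory

Thirty-four named signals are registered in three variants:

* `full_with_ips` — ankle flexion/inversion angle, angular velocity ω,
  angular acceleration α, moment and power (10); foot linear velocity,
  linear acceleration and angular velocity in AP/ML/vertical (9); shank
  linear velocity (3); in-pylon accelerometer AP/InfSup/ML and gyroscope
  coronal/sagittal/transverse (6); plus GRF and COP in three axes (6).
* `full_mc_only` — the six in-pylon channels replaced by motion-capture
  shank linear acceleration and angular velocity.
* `ips_only` — just the six in-pylon channels.

Kinematic/kinetic signals contribute four per-window statistics (mean,
sample sd, max, min); GRF/COP contribute mean and sd only. The feature
count is therefore 4·28 + 2·6 = 124 for the full variants and 4·6 = 24
for `ips_only`. Motion-capture signals live in the lab frame
(AP/ML/vertical, +ML lateral for every subject); in-pylon channels live
in the shank frame — the two sources are deliberately kept distinct.

## Preprocessing

* Zero-phase 4th-order Butterworth low-pass, 6 Hz for kinematics and
  20 Hz for force-plate channels. Zero-phase (forward–backward)
  application is the package default because windows are anchored to the
  heel-strike event and a one-pass filter's group delay would shift
  features relative to it; it can be disabled per `FilterSpec`. Two
  passes square the magnitude response, which the tests check against the
  analytic bilinear-warped Butterworth magnitude
  |H(f)|² = 1/(1 + (tan(πf/f_s)/tan(πf_c/f_s))^(2n)).
* GRFs and ankle moments are divided by body weight (mass·9.81 m/s²,
  i.e. weight, not mass).
* Ankle angles are referenced to their mean over an unloaded-swing
  interval, by default [−400, −250] ms before heel strike — late swing,
  ending exactly where the classification region begins. The interval is
  configurable; only its mean is used, so the operation is idempotent and
  disappears under differentiation.
* Derivatives (ankle ω, α) use central differences with second-order
  one-sided stencils at the ends, preserving series length so windows
  never straddle missing samples. Differentiation is performed on the
  real time base; time-normalization to the gait cycle is out of scope.

GRF/COP are assumed already decimated onto the 120 Hz kinematic time
base; the trial container holds a single shared sampling grid.

## Windowing

Windows are 150 ms (18 samples at 120 Hz) and advance one sample
(8.33 ms is interpreted as exactly 1/120 s, avoiding millisecond rounding
drift). Heel strike is snapped to the nearest sample; all window timing
is expressed relative to that sample. Two readings of the mid-swing rule
are implemented because the defining parentheticals ("at least half the
data during mid-swing", "less than half after heel strike") admit both:

* `span_rule` (default): start ∈ [−250, −75] ms, i.e. the window begins
  no earlier than 250 ms before heel strike and ends by +75 ms. 22
  windows per stride.
* `strict_rule`: start ∈ [−250, −192] ms and end ≤ +75 ms. 7 windows.

`span_rule` is the default because the classification region is described
as running from mid-swing up to 75 ms after heel strike. Both counts are
pinned by test against brute-force enumeration, and a closed-form count
(`midswing_window_count`) is property-tested against enumeration over
randomized specs. Boundary comparisons carry a 10⁻⁶ ms tolerance because
start times computed as `sample · 1000/f_s` carry float rounding.

## Classifier

Multi-class LDA with pooled within-class covariance (divisor n − K),
written from scratch. Class c scores

δ_c(x) = xᵀΣ_λ⁻¹μ_c − ½μ_cᵀΣ_λ⁻¹μ_c + ln π_c,
Σ_λ = (1−λ)Σ + λ·(tr Σ/p)·I.

Defaults: shrinkage λ = 10⁻⁴ (124 features can exceed per-class window
counts on small datasets, making Σ singular; the shrinkage is a numerical
safeguard with negligible bias, configurable to 0), empirical priors,
no feature scaling (plain LDA is scale-invariant at λ = 0; z-scoring is
available behind a flag for conditioning at larger λ). Ties break toward
the fixed class order eversion < flush < inversion. At λ = 0 predictions
are verified row-for-row against an explicit brute-force discriminant and
against scikit-learn on balanced instances (balanced because the
covariance-divisor convention shifts δ by a class-independent factor that
can only matter when priors differ).

A majority vote over the k most recent window predictions
(`majority_vote`, ties toward the most recent label) is provided as the
post-hoc smoothing a real-time controller would apply within a stride.

## Signal selection

Greedy wrapper selection at signal granularity (a signal's 2–4 statistics
move together, matching how rankings are reported). SFS adds, at each
step, the signal whose addition maximizes accuracy; SBS removes the
signal whose removal leaves the most accurate classifier — i.e. it
discards the least useful signal first, so the last survivor is the most
valuable. Ties break toward the lowest inventory index for
reproducibility. Candidate sets are scored either by leave-one-trial-out
cross-validation on the training data or on a fixed held-out dataset;
the same trial-level partition is used during selection as in final
evaluation so that window leakage cannot inflate pick accuracy.

## Evaluation

Accuracy = correctly classified mid-swing windows / windows evaluated;
confusion matrices are reported with rows = true terrain in the fixed
class order, plus per-terrain accuracies and their (min, max) range.
LOOCV leaves out one *trial* per fold by default: the 22 overlapping
windows of a stride are near-duplicates, and window-level folds would
leak them between train and test. Window-level LOOCV remains available
(`unit="window"`) for comparison. Folds whose training part loses a class
are skipped and listed in the report rather than silently imputed.

## Synthetic generator

Each signal is a sum of ≤3 harmonics of the stride frequency
(deterministic phases), a terrain effect δ·w(t) with w a sin² bump on
[−250, +75] ms around heel strike, a per-subject offset
u ~ N(0, τ²), and noise that is white or AR(1). Defaults mirror the
study scale: 3 subjects, 5 trials per class per subject, 120 Hz, 1.2 s
strides with heel strike at 0.8 s, flush as the zero-effect reference
and symmetric ±effects for the two slopes. The effect is localized in
late swing/early stance because that is where the classification region
looks; a generator whose class differences lay elsewhere would make
mid-swing classification impossible by construction.

The benchmark preset (`preset_discriminative`) seeds terrain information
in exactly three signals — ankle inversion angular velocity, foot
vertical velocity (positive polarity) and foot ML angular velocity
(negative polarity) — at amplitude 3× the noise sd, with AR(1) noise
(ρ = 0.9). AR(1) is used because adjacent 8.33 ms windows of real
kinematics are strongly correlated; white noise would make window-level
cross-validation look deceptively honest. Note two consequences the
reports make visible:

* the six in-pylon channels carry no terrain effect in this preset, so
  the `ips_only` classifier sits at chance on synthetic data — a
  designed contrast (informative vs noise signals), not an emulation of
  in-pylon performance on real gait;
* adding all 121 noise feature columns dilutes the classifier under
  leave-one-trial-out evaluation, so the full-inventory accuracy is lower
  than the informative-subset accuracy. The class-recovery benchmark is
  therefore defined on the discriminative signal set (what selection
  identifies), and the acceptance report lists both numbers.

Synthetic test-set analogues (`study_cohort`) shift the distribution the
way the study's test collections did: new subjects with doubled subject
offsets and slightly attenuated effects ("slope not visible"), and a
two-subject "prototype prosthesis" set with 20% weaker effects.

What passing these tests shows: the pipeline's arithmetic, its
event-anchored windowing, the classifier and the selection machinery are
correct on data with the assumed structure. What it does not show:
anything about real prosthetic gait — the generator has no gait-cycle
time warping, no GRF/dynamics consistency, no heel-strike detection
error, and its waveforms are not physiologically validated.

## Statistical choices

* Sample standard deviation (n−1) throughout.
* Chance-band checks use the 99% binomial interval around 1/3 with n =
  number of *trials*, not windows: window-level predictions are
  cluster-correlated within a trial, so trials are the honest effective
  sample size.
* The selection benchmark uses 20 seeded replicates, 6 signals with one
  informative, 3 subjects × 3 trials per class; the acceptance threshold
  (≥19/20 correct top ranks) tolerates one unlucky draw.

## Problem sizes

The default benchmark is 45 training trials (990 mid-swing windows ×
124 features), 15 + 24 test trials, and 20 selection replicates of 27
trials × 6 signals; the full test suite and the acceptance script each
complete in about a minute on one core. Full-inventory SFS/SBS
(analysis script 03) is the one expensive step (~2 min), quadratic in
the 34 signals with a 45-fold CV per candidate.

## Known limitations

* The supplementary-file reader ingests tab-separated text via an
  explicit dialect descriptor (column map + time column); it does not
  sniff unknown layouts, and the deposited datasets' internal structure
  is not modelled.
* Only the mid-swing classifier is implemented; other gait regions are
  enumerated but not classified.
* The in-pylon gyroscope is modelled with three angular-velocity planes,
  following the published rankings, although the hardware description
  mentions a bi-axial gyroscope; the discrepancy is inherited, not
  resolved.
* Heel-strike times are inputs; no event detection is performed.
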