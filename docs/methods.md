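# Methods

## Problem setting

A knee-ankle-foot orthosis carries 14 sensors: a three-axis accelerometer
and a two-axis gyroscope on each of the thigh and shank segments, rotary
potentiometers at the knee and ankle, and two insole force sensors, all
sampled at 500 Hz.  The task is to recognize the *initiation* of a
sit-to-stand (SiSt) transition early and without false positives, so that
a powered orthosis could trigger assistance safely.  The package contains
both the recognition algorithm and a synthetic-data generator that stands
in for the human recordings of the emulated protocol, which were never
published.

## The synthetic protocol

`orthosim.simulate_dataset` reproduces the study script: per subject,
activities 2, 3, 4, 6, 7 and 8 (scripted mixtures of sitting, standing,
short walks and transitions) once per each of five initial seated leg
positions, plus pure sitting (1) and three treadmill-walking trials
(5, 9, 10) — 34 one-minute trials per subject, ≈5.7 h for ten subjects.
Scripted SiSt events always start at t = 20 s and stand-to-sit events at
t = 40 s.

Kinematics are intentionally minimal — the generator's purpose is to
provide labeled, learnable signals with realistic confounders (gait
oscillations, stand-to-sit motion, sensor noise, baseline drift), not
biomechanical fidelity:

* Segment model: thigh and shank carry inclination-from-vertical angles;
  sitting holds the thigh at ~90°, standing at ~5°; the shank inclination
  is `knee − thigh`.  Accelerometers output the gravity projection on
  their axes in units of g plus a small motion term proportional to the
  segment angular rate, gait oscillation, 0.01 g slow sinusoidal drift and
  white noise (SD 0.05 g).  Gyroscopes output the segment angular rate
  plus noise (SD 5 °/s); potentiometers add 0.5° noise; force sensors 2 N.
* Knee trajectory: every transition follows a logistic curve between the
  position-dependent seated angle and the 5° standing angle, rescaled so
  its endpoints meet the neighbouring postures exactly (a raw logistic
  leaves a small step at segment boundaries which wavelet denoising smears
  into a spurious velocity plateau).  The steepness `s = duration / 9.2`
  keeps the raw endpoints within 1° while making the 5%-of-peak-velocity
  extent of the event match its scripted duration to well under 0.1 s.
* Seated knee angles: position 1 (legs bent under the chair) 110°,
  positions 2–4 90°, standing 5°.  Position 0 ("fully extended legs") is
  pinned at 50° as a simulator convention: it is the smallest seated angle
  for which the 45° midpoint rule still falls strictly inside the
  transition, and letting the knee rest below 45° would force either a
  discontinuity or a spurious downward 45° crossing when the leg extends
  again after sitting back down.
* Transition durations: drawn per event from a normal distribution around
  the subject's mean duration, truncated symmetrically (±0.58 s) so the
  truncation does not bias the mean.  "Fast transition" activities (6, 7)
  scale the draw by 0.7 and ordinary activities by 1.2; with the 15:10
  normal:fast mix of SiSt trials per subject the dataset mean equals the
  population mean of 1.30 s exactly, matching the reported duration
  statistic.  The subject means are drawn as N(1.30, 0.05²) s.
* Forces: each insole channel ramps between a seated baseline (15% of the
  standing load) and a body-weight-proportional standing load
  (heel 60% / toe 40% of half the body weight), oscillating in antiphase
  during gait.  Gait cadence is 95/110/125 steps per minute for the slow,
  normal and fast walking speeds, with per-subject jitter.

Everything is driven by `numpy` Generators seeded from a single integer;
identical parameters and seed give bit-identical output.

What the generator does **not** emulate: multi-joint biomechanics,
impaired or elderly movement, postural sway richer than low-frequency
wobble, sensor nonlinearity, or any correlation structure between
channels beyond the shared segment kinematics.  Passing tests on this
data therefore demonstrates the correctness and internal consistency of
the pipeline — not field performance on real orthosis recordings.

## Preprocessing and annotation

Denoising uses the stationary wavelet transform (db4, 4 levels,
variance-normalized) with a soft universal threshold per channel,
`λ = σ̂ √(2 ln N)`, σ̂ from the median absolute deviation of the finest
detail band — the standard translation-invariant (cycle-spinning)
recipe.  Signals are reflect-padded to a multiple of 2⁴ and cropped, so
boundary effects stay at the trial ends.  Note the transform is offline
(non-causal): a transition can pre-echo by up to ~0.25 s into the
preceding epoch, which occasionally lets the detector fire one epoch
before the annotated onset.

Epochs are non-overlapping 100-sample (0.2 s) windows; trailing remainder
samples are discarded.  An epoch inherits the label of the majority of
its samples; exact 50/50 ties label 1, favouring sensitivity.

The automatic annotator (standing in for the study's three human raters)
marks a SiSt midpoint at the first sample of a sustained downward crossing
of 45° knee flexion — sustained meaning the 0.25 s means before/after the
crossing lie above 46°/below 44° — and expands the region to where the
smoothed knee angular velocity (Savitzky–Golay, 201 samples, order 2,
first derivative) falls below 5% of the event's peak, tolerating
sub-threshold gaps of up to 0.05 s.  On 50 seeded trials the annotated
boundaries track the generative truth within 0.1 s and the midpoint angle
within 1°.  Upward crossings (stand-to-sit) are rejected by the
sustained-crossing test.

## Features, normalization, lags

Eleven statistics per channel and epoch, channel-major order: standard
deviation, entropy, coefficient of variation, mean, maximum, minimum,
median, slope, max/RMS, RMS/mean, fractal dimension.  Estimator choices
the feature list leaves open:

* entropy: Shannon entropy (bits) of a 10-bin equal-width histogram over
  the epoch's own range; 0 for constant epochs — the cheapest defensible
  estimator at 100 samples;
* slope: ordinary-least-squares slope versus time, reported per second so
  its units do not depend on the epoch length;
* fractal dimension: Higuchi's method with k_max = 8 (standard for short
  physiological windows); constant epochs report 1.0;
* ratio features guard near-zero denominators with 10⁻¹², keeping
  constant-zero epochs finite.

Normalization maps each column to [−1, 1] by its training min/max; both
endpoints are attained on training data, test values are *not* clipped,
and training-degenerate columns map to 0 (an uninformative feature gets a
neutral value).  Bounds are fitted per cross-validation fold, never on
test subjects — the study leaves open whether its bounds were global; the
per-fold choice prevents leakage and is flagged because it changes
numbers.

Lag concatenation builds row `e` from epochs `e−k+1 … e` (strictly
causal, a prerequisite for early detection); rows before the first full
window repeat row 0, preserving the row count.  `k` ranges 1–10.

## Feature selection

mRMR with the difference (MID) criterion: the first feature maximizes
`I(x; c)`; each next one maximizes `I(x; c) − (1/|S|) Σ_{s∈S} I(x; s)`.
Mutual information is the plug-in histogram estimate in bits over 10
equal-width bins of the training range (class labels used as-is); ties
break to the lowest column index.  On desk-scale hardware the estimate is
computed on a seeded subsample of at most 12 000 training rows, and the
ranking depth (default 60 columns) bounds the candidate pool handed to
the wrapper.

Forward feature selection then scans candidates in mRMR order with a
small probe ELM (100 hidden neurons, fixed seed, balanced class weights)
scored by F1 on one held-out training subject; a candidate is kept only
when it strictly improves validation F1, scanning stops after five
consecutive non-improvements or at the feature cap (default 30), and at
least one feature is always kept.  On the synthetic data this typically
retains 2–6 of the 1 232 lag-8 columns per stage (≥ 99.5% reduction; the
synthetic classes are far more separable than real recordings, so the
reduction is stronger than the 89–94% band reported on the original
data).

## Classifiers

**ELM** — input weights and biases drawn uniform(−1, 1) under a seed (one
row per hidden unit, so hidden layers are prefix-nested across sizes
sharing a seed); hidden activations are logistic sigmoids; output weights
solve the least-squares problem via SVD with relative cutoff 10⁻¹⁰
(equivalently `β = H⁺T`), optionally ridge-regularized.  Targets are
coded {−1, +1} with decision threshold 0 (scores of exactly 0 predict the
positive class).  The model enforces `L ≤ N`; at `L = N` it interpolates
the training targets exactly.  An optional balanced class weighting
solves the weighted least-squares problem giving both classes equal total
weight — used inside the cascade, where transition epochs are heavily
outnumbered.

**MLP** — one sigmoid hidden layer (`Z = f(Wx − θ)`), sigmoid output
thresholded at 0.5, trained by full-batch gradient descent on
cross-entropy with learning rate 0.01, momentum 0.9, at most 500 epochs
and early stopping (patience 20) on a 10% validation split when at least
10 samples are available.  Full-batch updates make training invariant to
row order under a fixed seed.  The training recipe is a package choice;
only the architecture and transfer functions are dictated by the method.

`select_hidden_neurons` picks the hidden-layer size by stratified 5-fold
cross-validation, minimizing mean validation error with ties to the
smaller count.  The cascade defaults to 300 hidden neurons per stage
(clipped to the training-set size) rather than re-running the grid inside
every fold.

## Two-stage cascade

Stage 1 (sitting vs everything else) classifies every epoch.  A state
machine enters a SITTING context after 3 consecutive sitting decisions
and leaves it after 10 consecutive non-sitting decisions (~2 s hangover)
without a detection; the hangover keeps stage 2 alive through the
transition onset, when stage 1 naturally flips.  Stage 2 (transition vs
non-transition) runs only inside the context; its first positive emits a
detection and closes the context until genuine sitting re-enters it, so
one sitting bout fires at most once.  Both gating parameters are
configurable; their defaults are package choices, as the gate's temporal
behaviour has no published specification.

Stage 2 trains on epochs whose trial time lies in sitting or SiSt
regions — negatives are pre-(and post-)transition sitting, positives are
transition epochs — matching the distribution the gate exposes it to at
run time.  Each stage owns its normalization bounds and selected feature
subset, fitted on training subjects only.

Epoch-level predictions reported for the cascade are the gated stage-2
decisions (0 wherever stage 2 did not run).  Because the gate disarms
after the first positive, later transition epochs count as misses; the
epoch-level recall of the cascade is therefore structurally low even when
every transition is detected — the transition-level counts are the
operative measure.

## Evaluation

Epoch level: a positive prediction in any epoch overlapping a transition
region counts as TP; false positives are counted only among epochs wholly
outside every region; TN/FN follow the epoch labels.  Accuracy, TPR, TNR
and F1 are the usual ratios (fractions internally, percentages at the
CLI).  Transition level: a trial containing a SiSt is TP_t when at least
one detection epoch overlaps the annotated region and failed-to-detect
(FTD) otherwise; a trial without a SiSt is TN_t when silent and FP_t when
any detection fires.  Detection time runs from the annotated region onset
to the start of the first in-region detection epoch (clipped at zero —
the epoch containing the onset scores 0) and is excluded for FTD trials.

`loso_evaluate` rotates each subject out in turn, refitting bounds,
selection and both stages per fold; epoch metrics are averaged over
folds, transition counts are summed over folds (and labeled as such),
detection-time statistics pool all detected trials.  The paired t-test
between per-subject F1 scores is two-tailed; all-zero differences return
p = 1 and constant non-zero differences return p = 0 with t = ±∞ (the
degenerate branches are defined explicitly because spreadsheet practice
is silent about them).

## Problem sizes and numerical choices

The bundled study-scale experiment uses 10 subjects × 34 trials
(≈5.7 h of 500 Hz signal, ~102 000 epochs) and runs the lag-8
leave-one-subject-out cascade in roughly ten minutes on one CPU core;
the test suite uses two-subject reduced protocols for the component
tests and the full protocol for the study-level checks.  Feature
matrices are stored as float32 (memory ~63 MB for the full dataset;
~0.5 GB transient per fold at lag 8).  Mutual-information ranking
subsamples rows as described above; the FFS probe caps its training rows
at 30 000.  SVD cutoff 10⁻¹⁰ relative; MLP validation split 10%;
histogram bins 10 throughout.

## Known limitations

* The simulator's separability is optimistic; the zero-false-positive,
  100%-detection result on synthetic data demonstrates the cascade
  mechanism, not clinical performance.
* Wavelet denoising is offline; a deployed system would need a causal
  filter, which would change detection latencies slightly.
* The annotator assumes one SiSt per sitting bout and a monotone knee
  descent; pathological or hesitant transitions are out of scope.
* Stand-to-sit events are modeled only as negatives and never detected as
  their own class.
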