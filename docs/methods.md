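# Methods

## Recording model and session format

A trial is three synchronized streams: EMG (6 channels, 1926 Hz,
millivolts), FMG barometric pressure (8 channels, 36 Hz, calibrated
arbitrary units) and IMU (12 channels, 36 Hz: 3-axis acceleration, angular
velocity, magnetic field, and Euler angles), plus a trigger track of
(label, onset) events marking the 12 instructed movements (11 hand/wrist/
forearm gestures drawn from the Fugl-Meyer assessment plus a no-motion
class, NM). The IMU is modeled exactly as the 12 listed channels; no
quaternion/Euler conversion is attempted.

Sessions are stored as a directory of CSVs plus `meta.json` rather than a
binary biosignal format: the files stay diffable and inspectable in tests,
and byte-stable float formatting (9 significant digits, C locale) makes
write→read→write a fixed point. Times are seconds as floats; sample
intervals are half-open `[start, end)` with stream-local 0-based indices,
which avoids off-by-one ambiguity when the same instant is mapped into two
sampling rates.

## Preprocessing

* **Segmentation** cuts each movement at `round(onset·rate)` per stream for
  the configured movement duration (default 6 s). Triggers past the end of
  the recording are dropped with a warning.
* **Trimming** removes the first 2 s and last 0.5 s of every movement:
  transitions between gestures produce bursty, atypical muscle activity,
  and impaired users start late. The retained 3.5 s at 1926 Hz is 6741 EMG
  samples.
* **FMG validity**: low-rate sample indices where any FMG channel leaves
  the session's valid measuring range (default (0, 115)) are marked; any
  frame whose low-rate window touches such an index is flagged
  `valid=False` and excluded from training/testing. The samples themselves
  are kept so indices stay aligned.

## Multirate windowing

EMG uses overlapped windows of 222 ms with a 55.6 ms step; FMG/IMU use
disjoint 55.6 ms windows. None of these durations are integer sample
counts, so the integer sizes are frozen once (round-half-up): **428-sample
EMG windows, 107-sample step, 2-sample low-rate windows**, and recorded in
every report. A trimmed 3.5 s movement yields `floor((6741−428)/107)+1 =
60` frames (the step divides 6313 exactly).

Each EMG frame is paired with the **latest disjoint low-rate window ending
at or before the EMG window's end time**, with low-rate windows laid out
from the segment's low-rate start. This is causal (the fused vector never
uses low-rate samples from after the EMG window) and keeps the two
modalities within one low-rate sample period of each other. Early frames
whose end time precedes the first complete low-rate window fall back to
that first window.

## Features

Per EMG channel and window, in frozen column order `[MAV, WL, ZC, SSC,
AR1..AR4]`:

* MAV `= (1/N)Σ|xᵢ|`, WL `= Σ|x_{i+1}−xᵢ|`;
* ZC counts sign changes `xᵢ·x_{i+1} < 0` whose step `|xᵢ−x_{i+1}| ≥ ε`;
* SSC counts interior extrema `(xᵢ−x_{i−1})(xᵢ−x_{i+1}) > 0` whose larger
  adjacent step `≥ ε`;
* ε defaults to 4·10⁻⁶ in the EMG stream's units. Both counts are
  homogeneous under joint scaling of signal and threshold (property-
  tested). The exact placement of the threshold (on the step vs. on the
  samples) varies across the time-domain-feature literature; both gates
  here sit on the adjacent differences and are config-isolated so they can
  be swapped.
* AR1..AR4: coefficients of x_t = Σₚ aₚ x_{t−p} + e_t estimated by the
  Burg recursion, chosen for stability on short 428-sample windows. The
  implementation is vectorized over whole batches of windows (the per-trial
  feature pass is a few tens of milliseconds) and matches the scalar
  reference implementation in statsmodels to machine precision; windows are
  demeaned first. Zero-variance windows yield zero coefficients and a
  `degenerate` flag rather than an exception mid-pipeline.

FMG and IMU contribute the MAV of each channel's 2-sample window. Total:
48 + 8 + 12 = 68 features per frame.

**Normalization.** Offline, every feature column is zero-mean/unit-sd
scaled *within each trial*; the applied (mean, sd) are stored so the
transform is invertible, and columns constant within a trial are set to 0
and logged. Per-trial statistics are acausal in a live stream, so the
simulated real-time path instead freezes statistics from the training
trials (their per-trial means/sds averaged) and applies those to test
frames; which statistics were applied is always recorded.

## Classifier

The core classifier is Gaussian equal-covariance LDA, written from the
discriminant δₖ(x) = xᵀΣ⁻¹μₖ − ½μₖᵀΣ⁻¹μₖ + log πₖ. (Some statements of
this equation drop the subscript on the first-term μ; the standard form
with μₖ is what the surrounding Bayes-decision derivation implies and what
is implemented.) μₖ are class means, Σ the pooled within-class covariance,
πₖ empirical frequencies (uniform by flag; the balanced design makes them
equal anyway). A 68×68 covariance pooled from a few hundred frames per
class is near-singular, so Σ is shrunk toward its own diagonal,
(1−λ)Σ + λ·diag(Σ), λ = 10⁻³ by default — small enough to leave
well-conditioned problems untouched (predictions are affine-invariant at
λ = 0, tested), large enough to rescue collinear feature sets; λ is stored
in every model artifact. Solves go through a Cholesky factorization;
singularity after shrinkage raises with advice to increase λ. Ties in
argmaxₖ δₖ resolve to the lowest class index, deterministically.

`ShrinkageLDA` follows the scikit-learn estimator protocol (`fit` /
`predict` / `decision_function`, `get_params`, trailing-underscore fitted
attributes) so it composes with sklearn tooling; `fit_lda`/`predict_lda`
are functional wrappers. The four baselines are scikit-learn estimators
frozen at: decision tree with entropy splits; 3-nearest-neighbors with
Euclidean distance; random forest with 40 trees and minimum leaf size 1;
linear-kernel SVM with C = 100. Feature ranking uses the frozen forest's
normalized Gini (mean impurity decrease) importances, truncated to the top
10 with each feature's modality tag.

## Evaluation protocols

* **Leave-one-trial-out CV**: each of the 5 trials is held out once; train
  and test frames both come from the trimmed [2 s, 5.5 s] cutout. Trials —
  never frames — are the CV unit, because overlapping windows within a
  trial are strongly dependent and frame-level CV would leak. The
  aggregated confusion matrix's accuracy equals the frame-weighted mean of
  fold accuracies (conservation-checked).
* **Sensor ablation**: LOTO accuracy for all 7 non-empty subsets of
  {EMG, FMG, IMU}, computed by masking columns of the already-extracted
  68-dim features (mask sizes 8/12/20/48/56/60/68).
* **Simulated real time**: per fold, a group-restricted model is trained on
  the other 4 trials' [2, 5.5] s frames; each held-out movement is decided
  by one majority vote over its first 10 frames starting 1 s after onset
  (frame 18 onward: 18·107 = 1926 samples = exactly 1 s). Vote ties break
  by the larger summed discriminant score. Each movement contributes
  exactly one decision per fold — no sliding re-votes.
* **Grouping**: the 12 labels are partitioned into four groups of three so
  that pairs known to be mutually confusable (CG–SG, TA–O, ME–HG, HG–MF,
  HG–NM, TA–NM, WE–FP) never share a group. The shipped default
  {MF,TA,WE} {ME,O,FP} {HG,CG,WF} {SG,FS,NM} satisfies every constraint;
  any override is validated and emitted into reports, and a grouping can be
  scored against a confusion matrix by its within-group off-diagonal mass.
* **Correlation**: Pearson r with the two-sided t-transform p-value
  (scipy), with input validation (length ≥ 3, non-constant).

## Synthetic generator

The generator emulates the *statistical structure the classifier assumes*,
not the physiology: per class a fixed signature — EMG activation per
channel in [0,1], FMG offset per channel, IMU offset per channel — with

* EMG as amplitude-modulated band-limited (20–450 Hz Butterworth) Gaussian
  noise, the standard surface-EMG surrogate, at amplitude 0.5 mV and a
  0.01 mV sensor-noise floor, with 0.25 s raised-cosine ramps at block
  edges standing in for the transition bursts that trimming removes;
* FMG as baseline 50 + offset (+ a slow sinusoidal drift, period 40 s,
  amplitude 0.25 ≈ 5% of the signature scale — the reason per-trial
  normalization exists) + unit-sd noise;
* IMU as offset + 0.5-sd noise;
* trial layout 12 × 6 s movements with 4 s rests (116 s), triggers at each
  onset; an optional flag clips a configured fraction of FMG samples out of
  range to exercise the validity rule.

The signature table is designed so the modalities must cooperate: CG and
SG share EMG/IMU signatures and differ only in FMG; MF and HG share
FMG/IMU and differ only in EMG; wrist/forearm movements carry the only
large IMU offsets; one EMG channel is exactly silent during WE so an
inactive channel is statistically identical to rest. An
`ImpairmentProfile` attenuates all signatures by γ ∈ (0,1] and can blend a
movement's signature toward its confusable partner (CG↔SG, TA↔O),
emulating weaker and less differentiated muscle activity. All randomness
flows through one seeded generator per (master seed, subject, trial);
regeneration is bit-identical.

What this does **not** emulate: motor-unit physiology, electrode shift,
sweat and contact artifacts, spasticity-induced co-contraction, IMU
kinematics through orientation integration, or inter-session variability.
Passing tests therefore demonstrate that the pipeline, features, models
and protocols are implemented correctly and behave as designed under the
assumed signal structure — not that any particular accuracy would be
achieved on clinical recordings.

## Problem sizes and numerical choices

Cohort-level checks use 10 subjects × 5 trials (the study-scale layout);
the end-to-end suite repeats them over 3 seeds and the impairment-recovery
check over 5 replicate cohorts with γ drawn uniformly from [0.3, 1].
Feature-oracle equivalence uses ≥1000 random windows (exact equality for
counts, 1e−10 for sums); AR recovery uses a 10⁵-sample simulated AR(4)
process (±0.02); the LDA-vs-Bayes comparison uses 10⁴ training and 10⁴
test points on correlated equal-covariance Gaussians (≤1 percentage
point). Degenerate inputs never throw mid-pipeline: zero-variance channels
produce zero features plus flags, constant columns normalize to zero with
a log entry, too-short segments yield zero frames with a warning.

## Known limitations

* The FMG deletion rule is range-based only; no artifact detection.
* Streaming normalization statistics are frozen from training trials; no
  adaptive re-normalization.
* The grouped protocol assumes each movement occurs exactly once per trial
  (the guided-training layout).
* `load_lda` reconstitutes the discriminant from stored moments; numeric
  round-trip is exact only to JSON float precision.
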