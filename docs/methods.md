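# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `maiju`, in the spirit of a methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

Recordings consist of four limb-sensor packet streams (timestamp,
3-axis accelerometer in m/s², 3-axis gyroscope in deg/s) at a nominal
52 Hz. Preprocessing is deterministic:

1. **Regularization.** Each stream is linearly interpolated onto the ideal
   grid t0 + i/52. The common base starts at the latest sensor start and
   ends at the earliest sensor end, so all 24 channels are defined
   everywhere; no extrapolation beyond a stream's packet span is performed.
   On inputs already sampled at the ideal base the operation is the
   identity.
2. **Gyro de-biasing.** The bias of each gyro channel is the median of its
   one-second window means over the lowest-motion decile of windows (motion
   ranked by per-sensor gyro variance). A stillness-based median is robust
   to movement outliers; accelerometer channels are untouched.
3. **Median smoothing.** A seven-tap running median per channel with
   reflect padding (length-preserving, no phase shift; idempotent on
   piecewise-constant signals).
4. **Framing.** 120-sample (~2.3 s) frames with a 60-sample hop. Frame i
   covers samples [60·i, 60·i+120); a trailing partial window is discarded.
   Frame center times join frames to second-level annotations; a frame's
   per-rater label is the category covering the largest share of its time
   interval (plurality, ties broken by the track's fixed class order), and
   frames with more than half of rater-time unlabeled are excluded from
   training and metrics.

The ordering — interpolate, de-bias, then median-filter — follows the
pipeline's listed text order; the median filter runs on the uniform base.

## Classifier

Per track (posture 7 classes, movement 9, carrying 2 after collapse), one
network: a frame encoder (three strided 1-D convolutions with leaky-ReLU,
widths 32/64/160, followed by temporal average pooling → a 160-dimensional
frame latent) and a temporal model (four dilated convolutions, width 64,
dilations 1/2/4/8, kernel 3, "same" padding) ending in a per-frame softmax.
The exact kernel widths are a documented in-package choice; the interface —
120×24 in, 160-d latent, per-track softmax — is the contract.

Training: ADAM (lr 1e-4, β1 0.9, β2 0.999, ε 1e-8), minibatches of 100
consecutive frames drawn from a single recording, weighted categorical
cross-entropy with inverse-frequency class weights normalized to mean 1
over present classes (absent classes are excluded from the loss, not given
weight 0 semantics of their own). Sample dropout (p = 0.3) zeroes random
time samples across all channels; sensor dropout (p = 0.3) independently
zeroes each sensor's six channels for a batch window — with p = 1 every
sensor is silenced, which is what makes the single-informative-sensor
ablation in the tests read at chance. 20% of labeled frames (frame-level
split) are held out for validation; the epoch maximizing validation
unweighted-average F1 is kept. The frame-level validation split mirrors the
stated recipe; it is not subject-disjoint and is therefore never used as a
generalization estimate — cross-validation is.

The default profile is 200 epochs at lr 1e-4. The package also ships
`SCALED_PROFILE` (12 epochs, lr 1e-3), the profile used by the test suite
on small synthetic corpora, where the posture task converges within a few
hundred gradient updates. Inputs are scaled per channel (accelerometers by
1/9.81, gyros by 1/100) so all channels enter the convolution at comparable
magnitude.

Cross-validation is at the subject level: folds partition subjects, never
recordings, and train/test subject disjointness is asserted inside the CV
loop. Ten-fold CV is refused below 10 recordings (use LOSO). The carrying
detector is binary — active carrying vs everything else — trained with the
same architecture and evaluated leave-one-subject-out; its predictions
gate which frames enter the recording-level distributions.

The networks run on `maiju.nn`, a small reverse-mode autodiff engine on
numpy arrays (broadcasted arithmetic, im2col convolution with stride and
dilation, GRU, fused softmax cross-entropy, ADAM). Gradients are verified
against central finite differences in the test suite.

## CPC

The self-supervised module reuses the frame-encoder architecture with a
128-dimensional latent, a single-layer GRU context model, and a linear
projection predicting the latent exactly k = 5 frames ahead (≈5.8 s at the
60-sample hop). The InfoNCE loss scores the true future latent against 10
negatives drawn uniformly from the same recording (implemented as draws
from the same-recording window batch, resampled per step), under dot-product
similarity with temperature 1. The chance baseline is ln(1+N) for N
negatives; the projection is initialized small so an untrained model sits at
that baseline. A single prediction head at distance k (not all 1..k) is
used. Latent extraction is a pure function of inputs and weights; the 2-D
embedding visualization of latents is out of scope — latents are exported
as arrays instead.

## BIMS

A recording's motor feature vector has 6 fused posture occupancies plus
6 × 7 posture-conditional fused movement distributions (48 features; left/
right intermediates fused). Conditional blocks of postures never observed
are zero-filled and flagged; in the masked representation they become NaN
and contribute no deviation terms to the likelihood — a never-standing
5-month-old is not scored on standing-conditional movement.

Age bins sit at 1-month steps from 4 to 16 inclusive (13 bins). Members are
recordings within ±1 month of the center; bins short of 3 members absorb
the nearest-age recordings until 3 (ties broken toward the younger
recording); all ages above 16 months pool into the 16-month bin, and
targets above 16 evaluate as 16. Per-feature means and SDs (diagonal
covariance) are computed with a 1e-4 SD floor. Prediction computes
diagonal-Gaussian log-likelihoods per bin — including the normalization
constant, so tighter bins weigh more; the alternative (dropping the
constant) would make weights depend only on standardized deviations —
subtracts the max before exponentiating (13 bins × ~40+ features would
underflow otherwise), normalizes to weights, and takes the weighted average
of bin centers. Features used in the likelihood are those finite in the
query and in every bin, keeping bin log-likelihoods dimensionally
comparable. BIMS = (age − 4) × 100/12, hence bounded in [0, 100] with
50 at 10 months.

Recording-length robustness draws, for each segment length, random-start
segments from each long recording, recomputes the distributions on the
segment (via cumulative joint counts, so the sweep is O(1) per segment) and
summarizes the absolute age error with median/IQR/range. The clinical-score
predictor (AIMS analog) reuses the same machinery with score bins of
configurable width in place of age bins.

## Agreement statistics and IAR

Fleiss' kappa has two forms, named and implemented distinctly: the standard
multi-rater form on the item × category rater-count table (computed via
statsmodels; seconds with any unlabeled rater are dropped), and the
two-rater specialization on a compounded confusion matrix (Cohen-type
chance correction), which is what human-vs-algorithm comparisons use.
Confusion matrices are summed across recordings before any statistic is
computed, which keeps rare classes from vanishing into per-recording
denominators. Per-class kappa is the one-vs-rest collapse of the compound
matrix. Metrics of empty classes are NaN (undefined), never 0.

IAR: uncontested frames (all raters agree) keep one-hot targets;
contested frames are re-targeted as the renormalized mixture
(1−α)·rater distribution + α·classifier posterior, with α = 0.5 by
default, iterating train → refine until fewer than 1% of valid frames
change (L1 > 0.01) or 3 iterations. The mixing-form and stopping rule are
this package's operationalization of the published refinement idea; α = 0
is the identity by construction.

## Evaluation statistics

Bland–Altman works on predicted − annotated fractions in percentage points,
with a two-tailed one-sample t-test (df = n−1) of zero mean error and a
±2 SD band; the monthly-change Δ overlay is the OLS slope of occupancy vs
age (pp/month). The ten dependent-overlapping-correlation tests
(Pearson–Filon, Hotelling, Williams, Olkin, Dunn–Clark, Hendrickson–
Stanley–Hills, Steiger, Meng–Rosenthal–Rubin, Hittner–May–Silver, and Zou's
CI) are implemented from their published formulas — no packaged
implementation exists in this environment — and are validated two ways:
all statistics are exactly 0 under the exact null, and each test's type-I
error over 2000 simulated null draws (trivariate normal, n = 60) must stay
within 0.05 ± 0.02. Spearman p-values use exact permutation for n ≤ 9 and
the t approximation above. Transition rates count label changes between
consecutive retained frames only — a gap left by carrying filtering never
counts as a transition.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
for every downstream check.

**State sequences** are semi-Markov: per-track geometric dwell times
(posture mean 15 s, movement 4.5 s, carrying 8 s) with successive states
drawn proportionally to the occupancy deficit against the age-dependent
prior. The deficit scheduler makes empirical occupancies converge at rate
~dwell/duration instead of 1/√n, so hour-scale recordings already track
their configured priors to within a few percent. The dwell means put
posture transitions near 3.6/min and movement transitions near 13/min.
Age priors use two curve families — logistic ramps for monotone categories
(prone and supine decreasing, standing and fluent increasing) and Gaussian
bells for developmentally transient ones (crawling and elementary movement
peaking around 10 months) — normalized per age. Movement priors are masked
by a posture-compatibility table (no fluent locomotion in supine or side
lying; rolling only from lying postures) and renormalized.

**IMU synthesis.** Each posture fixes a per-sensor gravity direction from a
documented lookup table (e.g., supine → all sensors +z; sitting → arms +x,
legs +z), giving every posture a distinct 12-dimensional static
accelerometer signature. Movement quality sets an oscillation tier
(still 0 < proto 0.5 < elementary 1.1 < fluent 2.2 m/s², with matching
gyro tiers), with per-segment lognormal amplitude draws (σ = 0.35) so
neighbouring tiers overlap — reproducing the easy-posture/hard-movement
structure of human annotation. Carrying adds a common-mode adult-gait
sinusoid (2 Hz while actively carried). Sensor noise defaults: accel
0.25 m/s², gyro 1.5 deg/s, gyro bias uniform ±3 deg/s, timestamp jitter
2 ms, packet drop 1%. With zero noise and zero dynamics the accelerometers
read exactly the gravity vector and the gyros exactly their true bias,
which the tests assert.

**Raters** observe the truth through Gaussian jitter of segment boundaries
(SD 0.5 s) plus per-second confusion sampling — the two dominant
disagreement modes of video annotation. The default confusions (posture
diagonal 0.99, movement 0.87, carrying 0.98) are calibrated so three
simulated raters reproduce the characteristic agreement levels of this
annotation task: posture kappa ≈ 0.95, movement ≈ 0.6.

**Cohorts** draw recording ages uniformly and perturb each simplex block of
the age-dependent mean feature vector with a Dirichlet of concentration 80
(infinite concentration returns the means exactly). Concentration 80 keeps
block SDs at a few percentage points — enough noise that LOSO recovery is a
real test, not an identity.

**What the generator does not emulate:** biomechanically realistic limb
kinematics, sensor saturation and temperature drift, infant-specific
idiosyncrasies (e.g., bottom-shuffling), and correlated rater errors.
Passing tests therefore demonstrate that the pipeline recovers the
structure the generator encodes — separable posture signatures, graded
movement dynamics, monotone/bell age trajectories — not clinical-grade
performance on real recordings.

## Problem sizes in the test suite

The suite exercises the full pipeline at sizes chosen to keep the default
run at desk scale: ten 10-minute recordings for the cross-validated posture
check (subject-level ten-fold CV, 12-epoch scaled profile), three 5-minute
recordings for CPC learning, a 60-recording cohort for BIMS LOSO recovery,
twelve 125-minute state sequences at 100 resampling iterations for the
length-robustness sweep, and 2000 replicates for the type-I calibration of
the statistical tests. The full-scale training profile (200 epochs) and the
1000-iteration robustness sweep remain available through parameters.

## Known limitations

- The numpy networks are CPU-bound and deliberately small; they demonstrate
  the architecture contract and learnability, not state-of-the-art HAR
  accuracy.
- Gyro bias estimation assumes some genuinely still seconds exist; a
  recording with continuous vigorous movement would bias the estimate.
- The Gaussian normative model treats features as independent (diagonal
  covariance) and is sensitive to cohort coverage: sparsely populated age
  bins inherit nearest-age recordings, flattening the local age gradient.
- Fleiss' kappa on the multi-rater form drops seconds with any unlabeled
  rater rather than reweighting.
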