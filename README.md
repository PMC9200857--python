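# maiju — infant-wearable movement analytics

`maiju` implements an analysis stack for multi-sensor infant wearables of
the MAIJU type (a jumpsuit with one inertial sensor proximally on each
limb): from raw accelerometer/gyroscope packet streams to second-level
posture and movement classification, carrying-filtered recording-level
motor-ability distributions, and an age-normative motor maturity score
(BIMS). It is aimed at researchers in infant motor development and
wearable-based human activity recognition who need the full pipeline —
including a synthetic-data generator — without access to clinical
recordings.

## What it computes

**Signals.** Four limb sensors stream tri-axial acceleration (m/s²) and
angular velocity (deg/s) at a nominal 52 Hz. Preprocessing linearly
interpolates the packets onto a common ideal 52 Hz base, removes the
per-channel gyroscope bias, applies a seven-tap median filter, and cuts the
24-channel signal into 2.3-s frames (120 samples, 50% overlap).

**Classification.** A convolutional encoder fuses each frame into a
160-dimensional latent vector z_t; a dilated temporal convolution stack
models frame-to-frame dynamics and emits per-frame softmax probabilities
for each track (posture: supine/prone/side/crawl/sitting/standing plus
intermediates; movement: still/proto/elementary/fluent plus intermediates;
carrying). Training uses ADAM with weighted categorical cross-entropy,
sample and sensor dropout, and validation-based epoch selection; a binary
active-carrying detector (ACD) filters out frames where the infant is moved
by an adult. A contrastive-predictive-coding (CPC) module verifies that the
motor categories are present in the signal structure without labels: a GRU
context c_t predicts the latent z_{t+k} (k = 5 frames ≈ 5.8 s) against 10
negatives under the InfoNCE loss, whose chance level is ln(11).

**BIMS.** Each recording is reduced to its motor feature vector — fused
posture occupancies and posture-conditional movement distributions over
retained frames. For every 1-month age bin between 4 and 16 months, a
diagonal-covariance Gaussian is fit over the recordings within ±1 month of
the bin center (padded to ≥3 members with nearest-age recordings; σ floored
at 1e-4; ages >16 pool into the 16-month bin). A recording's motor-ability
age is the likelihood-weighted average of bin centers, and

    BIMS = (predicted_age_months − 4) × 100 / (16 − 4)

maps it onto a bounded 0–100 maturity scale (0 ≈ 4-month-old ability,
100 ≈ 16-month ceiling).

**Statistics.** Fleiss' kappa on compounded confusion matrices,
per-class recall/precision/F1/kappa, iterative annotation refinement (IAR)
of contested multi-rater frame labels, Bland–Altman agreement with a
zero-mean t-test, monthly-change Δ slopes, Pearson/Spearman correlations,
the ten-test battery for comparing dependent overlapping correlations,
quadratic age-trajectory fits, and posture/movement transition rates.

## Worked example

```python
import numpy as np
from maiju import SimConfig, simulate_state_sequence, synthesize_imu, simulate_raters
from maiju.io import RawPacketStream, preprocess
from maiju.annotations import fleiss_kappa
from maiju.simulate import generate_age_cohort
from maiju.bims import loso_evaluate, AgeNormativeModel, compute_distributions
from maiju.stats import transition_rates

# a synthetic 10-minute recording of an 11-month-old
cfg = SimConfig(age_months=11.0, duration_s=600, seed=42)
seq = simulate_state_sequence(cfg)
rec = synthesize_imu(seq, cfg)
streams = {k: RawPacketStream(k, v) for k, v in rec.streams.items()}
frames = preprocess(streams)
print(f"frames: {frames.frames.shape}")

ann = simulate_raters(seq, n_raters=3, seed=1)
print(f"posture kappa: {fleiss_kappa(ann, track='posture'):.3f}")
print(f"movement kappa: {fleiss_kappa(ann, track='movement'):.3f}")

tr = transition_rates(seq.posture, seq.movement, step_s=1.0)
print(f"transitions/min: posture {tr.posture_per_min:.1f}, movement {tr.movement_per_min:.1f}")

mfv = compute_distributions(seq.posture, seq.movement, retained=seq.carrying != 4)
cohort = generate_age_cohort(60, (4, 16), seed=0)
model = AgeNormativeModel().fit(cohort.X, cohort.ages)
pred = model.predict_bims(mfv.with_nan_unsupported())
print(f"predicted motor age: {pred.predicted_age:.1f} months  BIMS: {pred.bims:.1f}")

res = loso_evaluate(cohort.subjects, cohort.ages, cohort.X)
print(f"cohort LOSO: r = {res['pearson_r']:.3f}, MAE = {res['mae']:.2f} months")
```

prints

```
frames: (518, 120, 24)
posture kappa: 0.909
movement kappa: 0.583
transitions/min: posture 3.6, movement 13.0
predicted motor age: 10.0 months  BIMS: 50.0
cohort LOSO: r = 0.985, MAE = 0.45 months
```

The 600-s recording yields 518 overlapping frames. Three simulated raters
agree almost perfectly on posture (kappa ≈ 0.9) and far less on movement
quality (kappa ≈ 0.6) — the characteristic asymmetry of second-level video
annotation. The recording transitions posture ~3.6 times and movement ~13
times per minute. The 11-month recording's motor distributions place its
motor-ability age at 10.0 months (BIMS 50); across a 60-recording cohort,
leave-one-subject-out age prediction correlates with true age at r ≈ 0.99
with a mean absolute error under half a month.

A command-line interface wraps the common steps:

```bash
maiju simulate --age 11 --duration 600 --seed 42 --out rec/
maiju preprocess --in rec/ --out frames.npz
maiju agreement --ann rec/annotations.csv --track posture
```

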