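# Methods

## Problem and model

The package estimates sagittal-plane hip, knee and ankle angles (degrees;
flexion and dorsiflexion positive) during treadmill running from the raw
3-axis acceleration of a single shoe-mounted sensor sampled at 100 Hz.
The estimator is a windowed regression: each 600 ms acceleration window
(60 samples, centred so it covers 30 past samples including the centre
and 30 future samples) is mapped by a 1-D CNN to the angle triple at the
window's centre time.  The four input channels are the three sensor axes
plus the resultant `a_xyz = √(ax²+ay²+az²)`; the resultant is invariant
to sensor orientation, which makes the input partly robust to differences
in how the sensor sits on the shoe between runners.

Architecture (valid convolutions, kernel 3, stride 1):

| layer | output shape | setting |
|---|---|---|
| input | (60, 4) | |
| dropout | (60, 4) | rate 0.1, inter-participant only |
| conv1d | (58, 50) | ReLU |
| conv1d | (56, 50) | ReLU |
| maxpool | (28, 50) | size 2, stride 2 |
| conv1d | (26, 100) | ReLU |
| conv1d | (24, 100) | ReLU |
| flatten | 2400 | |
| dense | 100 | ReLU |
| dense | 3 | linear |

All trainable layers use Xavier-normal initialisation.  Training uses
Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7), batch size 512, 50 epochs, no
early stopping, no validation monitoring, no input normalisation.  The
loss is the joint-weighted sum of per-joint batch RMSEs,
`L = (3·RMSE_hip + 1·RMSE_knee + 3·RMSE_ankle)/3`, computed per
mini-batch (the only choice compatible with stochastic gradients).  RMSE
means root-*mean*-square throughout: NRMSE percentages are only
dimensionally sensible with the mean inside the root.  The flatten step
is a pure reshape — an activation there would be a no-op after two ReLU
layers.  Max-pool size/stride of 2 and the "valid" padding follow from
the layer-shape table (56→28 and 60→58→56).

Because no deep-learning framework is a dependency, the network — im2col
convolutions, backpropagation, Adam — is implemented in NumPy.  This
keeps runs bitwise deterministic for a fixed seed and single-threaded
BLAS, and the backward pass is verified against finite differences in the
test suite.

## Preprocessing

All channels (acceleration, reference angles, heel height) are low-pass
filtered with a 4th-order Butterworth at 6 Hz applied forward–backward
(zero phase).  Causal filtering would delay the acceleration relative to
the angle targets by the group delay and corrupt the pairing; the price
is that the effective magnitude response is the squared 4th-order
response.  The resultant channel is derived *after* filtering so channel
4 always equals the root-sum-square of channels 1–3.  Windows never cross
trial boundaries; edge positions that cannot host a full window are
dropped rather than padded, so a trial of T samples yields T−59 windows.

Two evaluation protocols are supported.  The intra-participant 80/20
split assigns *whole trials* (shuffled, nearest-trial rounding, at least
one test trial).  A per-window random split is also provided for
comparison but warns when used: windows one sample apart share 59/60
samples, so randomly splitting windows leaks training data into the test
set.  Leave-one-subject-out (LOSO) folds hold out every participant once;
the input dropout layer is enabled only for LOSO models, where
generalisation to an unseen runner is the bottleneck.

## Scoring

Per participant and joint: RMSE (deg); NRMSE = 100·RMSE / (max−min) of
that participant's *reference* test angles; R² = 1 − SS_res/SS_tot ("R²"
is read as the coefficient of determination — it is described as a
goodness-of-prediction measure with values like 0.97, which matches that
reading).  Across-participant summaries are means with SDs of the
per-participant values.

Six discrete events are read off each IC-to-IC stride: peak hip flexion,
peak hip extension (magnitude of the most negative hip angle), peak knee
flexion within stance, peak ankle dorsiflexion, peak ankle
plantarflexion (magnitude), and the signed ankle angle at initial
contact.  Initial contacts are per-stride minima of heel height, found
with a minimum separation of half the dominant stride period (estimated
by autocorrelation over 0.3–2 s lags); flat or aperiodic series raise an
error.  Toe-off is never measured, so stance is taken as the first 40 %
of the stride after IC (typical for running; configurable).  Estimated
and reference events are paired stride-by-stride via IC proximity
(within half a stride); summaries report reference/estimated means, MAE
and the signed mean difference, with SDs across strides and, at report
level, across participants.

## Synthetic data generator

The generator replaces the original 10-runner motion-capture dataset
(10 participants × 5 speeds, 8–12 km/h × 3 trials × 60 s at 100 Hz —
the default `SynthConfig`).  What it emulates:

* **Angle waveforms.** Each joint is a smooth stride-periodic curve —
  hip: two harmonics; knee and ankle: periodic von-Mises-style bumps at
  canonical stride phases (knee stance bump ≈ 15 % of stride, swing bump
  ≈ 70 %; ankle dorsiflexion peak ≈ 20 %, plantarflexion peak ≈ 40 %).
  Each participant's curves are affinely calibrated on a dense phase grid
  so the per-stride extrema equal that participant's event values
  *exactly*; a narrow bump pinned at the initial-contact phase sets the
  at-IC ankle angle without moving the extrema (perturbation < 1e-8 deg).
* **Population variability.** Event values are drawn per participant as
  independent normals with the reference means and between-participant
  SDs — hip flexion 27.6 (7.3), hip extension 15.3 (3.9), stance knee
  flexion 30.1 (6.4), dorsiflexion 12.8 (3.6), plantarflexion 21.4 (5.0),
  at-IC 2.2 (3.1) deg — plus mild physiologic clipping whose bias on the
  population means is a small fraction of a degree.  No covariance
  structure between events is imposed.  Shape/timing parameters and
  anthropometry (thigh/shank ≈ 0.42 m, foot ≈ 0.25 m) are jittered per
  participant.
* **Cadence.** Stride rate is `cadence_base · (1 + 0.025·(v − 10))` with
  cadence_base ~ N(1.40, 0.06) strides/s, so cadence rises monotonically
  over 8–12 km/h.  The stride period is quantised to whole samples, which
  makes noiseless trials exactly stride-periodic and puts initial
  contacts on exact sample indices (stored as ground truth).
* **Accelerometer.** A planar thigh–shank–foot chain is planted under the
  angle trajectories; the pelvis vertical trajectory is chosen so the
  chain's heel point follows a prescribed heel-height curve whose minimum
  falls exactly at IC.  The sensor point rides rigidly on the foot
  segment; its world acceleration comes from 4th-order central
  differences of the closed-form trajectory (stencil 1 ms), gravity is
  added, and the specific force is rotated into the foot frame — so the
  signal has the structure of a real shoe-mounted accelerometer: m/s²,
  gravity included, impact-free but strongly phase-locked to the gait
  cycle.  A smooth mediolateral component and i.i.d. Gaussian noise
  (default SD 0.8 m/s², a deliberately generous figure standing in for
  sensor noise plus mounting vibration) complete the three channels.

What it does **not** emulate: impact transients and soft-tissue
artefact, stride-time variability within a trial, frontal/transverse
kinematics coupling into the sagittal signal, treadmill-vs-overground
differences, sensor-mounting drift within a session, and any correlation
structure between event values.  Passing tests on this simulator
therefore demonstrate that the pipeline is implemented correctly and can
recover a physically-coupled acceleration→angle mapping — not that the
accuracy figures transfer to real runners.  The deterministic
angle↔acceleration link also makes the synthetic task easier than the
real one, which is why desk-scale intra-participant errors here are
smaller than accuracies reported on real data.

## Numerical choices and degenerate inputs

* Dense calibration grid of 100 001 phase points; at 100 Hz sampling the
  worst-case discretisation error of a sampled extremum is ≈ 0.2 deg
  (curvature-limited), inside the 0.5 deg event-oracle tolerance.
* Double time-integration of the noiseless world-frame acceleration
  recovers the sensor path to < 1 % relative RMS over a stride
  (trapezoid error at 100 Hz for ~1.4 Hz content).
* Filtering requires > 3·(2·order+1) samples; cutoffs at or above
  Nyquist, empty batches, constant reference series (R², NRMSE), flat or
  monotone heel series, and single-participant LOSO all raise errors
  rather than returning silently wrong numbers.
* Loss gradients treat a zero per-joint RMSE as gradient zero (the
  subgradient at the kink).
* All randomness flows from explicit seeds (population, per-trial noise
  derived from the profile seed + trial index + speed, shuffling,
  initialisation, dropout) via `SeedSequence`, so every artefact is
  reproducible bit-for-bit in a fixed environment.

## Desk-scale experiment sizes

The full protocol (150 trials × 60 s, 50 epochs) is hours of CPU; the
shipped `scaled_config` preset — 4 participants, 2 speeds × 2 trials ×
30 s, noiseless, 20 epochs, batch 128 — is the package's standard
self-check and what `scripts/acceptance.py` runs.  Training windows are
thinned (every 2nd window intra, every 3rd LOSO) because single-sample-
stride windows are ~98 % redundant; evaluation always uses every test
window.  On one CPU the preset trains a fold in well under a minute and
the full intra+LOSO comparison lands in minutes, reproducing the
qualitative structure of the full-scale study: near-ceiling
intra-participant accuracy and a several-degree LOSO error driven by
between-participant waveform differences.

## Known limitations

* The simulator's smooth forward model lacks impact content; models
  trained on it will not transfer to real sensors.
* LOSO accuracy on 4 synthetic participants is noisy across seeds; only
  the intra < LOSO ordering is treated as stable.
* The NumPy network is single-threaded and tuned for this architecture
  only (e.g. max-pool requires size = stride).
* Trials resampled from other rates are not handled beyond what the
  filter spec supports; the pipeline assumes 100 Hz throughout.
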