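# Methods

## Overview

`gaitsynth` studies a data-efficiency question in wearable-sensor
biomechanics: can sequence models that estimate 3-DoF hip and knee rotations
from inertial measurement unit (IMU) streams be trained on *synthetic*
sensor data — IMU signals computed from augmented joint kinematics through a
rigid-body model — instead of, or in addition to, measured recordings?  The
package implements the full loop: a gait cohort generator with known ground
truth, forward kinematics and virtual-IMU simulation, kinematic
augmentation, preprocessing into fixed-size training tensors, a BiLSTM
regressor, and the statistical comparison of training-set variants.

## Rigid-body model and frames

The lower limb is a serial chain pelvis → thigh → shank → foot (left side
only).  Hip and knee carry three rotational degrees of freedom, the ankle is
a hinge; seven joint angles total, always ordered
`hip_flex, hip_add, hip_rot, knee_flex, knee_add, knee_rot, ankle_flex`
(degrees).

* Earth frame: X along the walking direction, Y to the left, Z up.
* Segment frames sit at the proximal joint centre and coincide with the
  earth frame in the neutral pose; the distal joint centre lies at
  (0, 0, −L).
* 3-DoF joints decompose as an intrinsic Y–X–Z Euler sequence: flexion
  about the mediolateral axis, then ad-abduction about the anterior axis,
  then axial rotation about the longitudinal axis.  Signs are chosen so
  positive hip flexion moves the thigh forward and positive knee flexion
  folds the shank backward.  No community standard fixes these conventions
  uniquely; the pipeline only requires self-consistency, and a round-trip
  property test (forward kinematics → Euler extraction) guards the choice.

Joint-angle trajectories are represented as cubic splines, so poses exist
at arbitrary times and differential kinematics are analytic: angular
velocities propagate down the chain as ω_child = ω_parent + R·ω_rel with
ω_rel built from the Euler-rate kinematics, and accelerations use
a_child = a_parent + α×r + ω×(ω×r).  Because these are exact derivatives of
the interpolated motion, an *independent* finite-difference recomputation
(orientation difference quotients; a dense global position spline) agrees
to better than 1e−3 rad/s and 1e−2 m/s² on random smooth trials — this
dual-route check is run both in the test suite and by `validate-sim`.

## Virtual IMU convention

Each of the four sensors (posterior pelvis, lateral thigh, lateral shank,
dorsal foot — package defaults, configurable) reports

* **gyroscope**: segment angular velocity rotated into the sensor frame,
  `R_sensorᵀ ω_earth` (rad/s);
* **accelerometer**: *free* acceleration of the mount point — the second
  time derivative of its earth-frame position, **without gravity and in the
  earth frame**.

Many commercial IMUs instead output specific force in the sensor frame;
the convention here matches the frame in which simulated and measured
signals are compared in this pipeline and is stated on the API.  Native
simulation rate is 100 Hz.  No magnetometer, bias random walk or
orientation-filter model is included: the emulated sensors represent
research-grade units with on-board fusion.

## Measured-sensor emulation

A fully synthetic cohort must play both the "measured" and the "synthetic"
role of the experiment.  `emulate_measured` layers onto a clean trace:

* white Gaussian noise per channel, default σ_gyro = 0.03 rad/s and
  σ_acc = 0.2 m/s² — an order of magnitude below typical gait signal RMS
  (≈0.8 rad/s, ≈1.2 m/s² in the generated cohort), appropriate for fused
  research-grade sensors;
* one mount-misalignment rotation per trial, per-axis N(0°, 2°), applied to
  both channel triplets;
* optionally, an exponentially damped sinusoid (f₀ ≈ 10 Hz, ζ ≈ 0.3)
  injected into the acceleration at each heel strike as a soft-tissue
  artifact; off by default.

Noise is injected *before* the 6 Hz low-pass, mirroring a real acquisition
chain.

## Synthetic cohort generator

The generator emulates a 30-subject, three-speed laboratory walking study
with full ground truth; all of its numbers are package configuration values
shaped after normative adult gait, not measurements:

* per-DoF periodic keypoint curves (e.g. knee flexion: ≈20° loading
  response, ≈62° swing peak) interpolated by periodic cubic splines;
* anthropometry per subject: thigh ~N(0.42, 0.02) m, shank ~N(0.41, 0.02) m,
  pelvis half-width ~N(0.12, 0.01) m, foot ~N(0.25, 0.015) m;
* subject individuality: ±10 % amplitude scaling, ±3 % cycle phase shift
  and ~N(0°, 1.5°) postural offset per DoF — this is what creates the
  train/test generalisation gap the experiment needs; a
  `subject_variability` knob scales it (0 ⇒ identical subjects, the null
  case);
* speed classes slow / self-selected / fast with cycle durations 1.3 /
  1.1 / 0.9 s, stride lengths 1.10 / 1.25 / 1.45 m and mild sagittal
  amplitude scaling; stride-duration jitter σ = 3 %, with stride-level
  amplitude/offset perturbations interpolated across each stride so traces
  stay continuous;
* pelvis root motion: forward progression plus small vertical (±2 cm at 2
  cycles/stride), lateral, yaw/pitch/roll oscillations.

Each continuous trial stores exact heel-strike indices, computed as the
heel-height minimum inside each generated stride window.  The default
calibration (30 subjects × 3 speeds × 11 trials × 5 strides) yields 3960
usable strike-to-strike cycles, the scale of a single-site gait study.

What the generator does **not** emulate: pathological gait adaptations,
marker trajectories, ground-reaction mechanics, genuine soft-tissue
dynamics, real between-lab sensor variety.  Passing tests therefore show
that the method behaves as designed under controlled conditions, not that
a specific clinical accuracy would be reached on real patients.

## Heel-strike detection and segmentation

Strikes are local minima of heel height with ≥5 cm prominence and ≥0.7 s
spacing.  Walking stride times sit between roughly 0.85 and 1.4 s, so the
spacing rule keeps exactly the deepest minimum per cycle and discards the
shallow terminal-swing dip; the prominence floor rejects flat or noisy
traces.  Cycles span strike to strike; anything longer than 200 samples at
100 Hz is rejected with a warning.

## Augmentation operators

Five operators create synthetic kinematics from a source cycle (all draws
shared across the seven angle columns of a trial):

| operator | construction |
|---|---|
| magnitude offset | one δ ~ N(0°, 5°) added to every sample of every column |
| magnitude warp | natural cubic spline through 7 knots ~ N(1, 0.2), uniformly spaced endpoints included, multiplied element-wise |
| offset + warp | warp first, then offset |
| time warp | spline through 7 knots ~ N(1, 0.2); τ = cumsum/n, clamped to [0, 1]; angles and pelvis pose resampled at τ |
| time + magnitude warp | time warp first, then magnitude warp |

Design choices the operators' definition leaves open, fixed here: knots
include both endpoints at i/6 fractions; the time-warp index convention
makes constant knots = 1 the exact identity; warped trials are re-gridded
onto their original sample count (downstream packing expects per-cycle
sequences); the pelvis root pose is time-warped together with the joints
(rigid consistency) but never magnitude-warped or offset; a per-column
offset mode exists behind a flag.  Deliberately, **no plausibility filter**
is applied — extreme draws pass through.

Label consistency is structural: augmented trials carry only kinematics,
and their IMU signals are regenerated through the rigid-body model, never
warped directly.

## Preprocessing and packing

IMU channels are resampled by cubic splines where rates differ and both
IMU channels and angle labels are low-pass filtered with a second-order
Butterworth at 6 Hz, applied forward-backward (zero-phase) because the
pipeline is offline and phase lag would misalign inputs and labels.  The
effective gain is |H|² of the digital filter: ≈0.45 % at 20 Hz (the analog
prototype's value is ≈0.8 %; the bilinear transform attenuates faster) and
>98 % at 1 Hz.  Filtering happens once, at the training-preparation stage.

Training samples are 200 × 24 input matrices — sensor-major blocks
[acc x, y, z, gyro x, y, z] for pelvis, thigh, shank, foot — and 200 × 3
targets (one joint), zero-padded at the tail with a validity mask; padded
rows are exactly zero by contract.  Splits are subject-wise, and synthetic
samples are generated only from training-subject strides (a leakage guard
asserts this on provenance tags).

## BiLSTM regressor

Architecture: one or more bidirectional LSTM layers (hidden size H per
direction), a per-timestep fully connected layer 2H → H with tanh, dropout
0.5, and a linear H → 3 output.  Tuned sizes: hip 1 × 32, knee 1 × 128
(the desk-scale experiment default uses 32 for both).  Optimisation: Adam,
learning rate 0.001, β₁ = 0.9, β₂ = 0.999, batch 50, 100 epochs at full
scale.  The loss is mean-squared error over *valid* timesteps only
(an unmasked mode exists for comparison; on padded desk-scale data it
changes hip RMSE by well under the between-variant differences).

The network, backpropagation through time and Adam are implemented
directly on numpy arrays (float32 by default; float64 available and used
by the finite-difference gradient checks in the tests).  Inputs are
z-scored per channel with training-split statistics — rad/s and m/s²
channels differ by an order of magnitude, and without normalisation
training is unstable — and targets are z-scored symmetrically, with
predictions mapped back to degrees.  Padded rows remain exactly zero after
normalisation.  The first FC layer uses tanh and biases; both are config
choices, not canon.  Training is deterministic under the configured seed.

Hyperparameter search: subject-wise 5-fold cross-validation over an
(n_layers, hidden) grid, selecting the minimum mean validation RMSE with
ties broken toward the smaller model.

## Evaluation and statistics

Per test cycle and DoF: Pearson r, RMSE (degrees) and nRMSE, defined as
100·RMSE/(max − min) of the reference within the cycle.  Range
normalisation is the dominant convention in this literature and makes
small-range DoF (axial rotations) show large nRMSE, as expected; a
constant reference leaves nRMSE undefined and the cycle is flagged and
excluded from nRMSE aggregates.  Tables report mean ± sample standard
deviation (ddof = 1) per variant, joint and DoF, plus per-joint averages.

Variants are compared with a one-way MANOVA (statsmodels; Wilks' Λ with
the F approximation) on the six-dimensional per-cycle RMSE vectors —
per-cycle rather than per-subject vectors are the unit of observation
(a per-subject aggregation can be applied to the records before the call)
— followed by per-DoF ANOVA and Tukey HSD at α = 0.05.  A hand-rolled
Wilks' Λ (determinant ratio) backs a permutation cross-check in the tests,
and guards the degenerate cases: exactly identical groups short-circuit to
Λ = 1, p = 1; a singular within-group covariance skips the MANOVA with a
diagnostic and keeps the univariate tables.

## Desk-scale experiment sizes

The full study design (30 subjects, ~4000 cycles, hidden 128, 100 epochs)
is reproducible with this package but the default `ExperimentConfig` is
desk-scale so a complete 3-variant × 2-joint experiment runs on a laptop
CPU in minutes: 8 subjects × 3 speeds × 2 trials × 4 cycles ≈ 192 cycles,
5:1 augmentation of the 6 training subjects (≈720 synthetic cycles),
hidden 32, 20–50 epochs.  The acceptance script uses the same sizes.  At
this scale the directional result is stable: training on
measured+synthetic data yields a lower hip-average RMSE than measured-only
training (typically ≈1.9° versus ≈3.3°, a ~40 % reduction).

## Numerical notes and limitations

* Spline-represented angles have jerk discontinuities at the 100 Hz knots;
  analytic propagation avoids the second-derivative noise a finite
  difference would pick up there.
* Quaternions are scalar-last (scipy convention) throughout; pelvis
  orientation interpolation uses rotation splines, which are exactly
  equivariant under a change of earth frame.
* The time-warp τ is clamped, not rescaled, so strong draws can flatten
  the first/last samples of a warped cycle.
* `emulate_measured` applies the misalignment rotation to the earth-frame
  acceleration as well, modelling an imperfect earth-frame alignment; a
  physically distinct effect (sensor repositioning) would also shift the
  lever arm, which is not modelled.
* The statistical comparison treats cycles as independent observations;
  cycles from one subject are correlated, so the MANOVA p-values on the
  synthetic testbed are optimistic — the directional conclusions are the
  robust output.
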