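# Methods

This note documents the processing model implemented in `qstm`, the
parameters that matter, the synthetic device model used for validation,
and the design decisions taken where the device's published description
leaves the behaviour open.

## Signal chain and rates

The device produces load-cell voltages at a 500 Hz master rate; inertial
fusion runs at 200 Hz; the processed output stream is decimated to
100 Hz. The implementation runs everything on the 500 Hz master clock:
the fusion filter consumes the master stream in alternating groups of
2 and 3 samples (averaging the gyro samples in each group, which is the
natural anti-alias for a rate signal) and uses the actually covered
interval (4 or 6 ms, derived from index arithmetic, never from file
timestamps) as its integration step; the output takes every 5th master
tick. No interpolation is performed anywhere.

## Attitude estimation

Attitude is a unit quaternion `(q0, q1, q2, q3)` mapping device-frame
vectors to the global (gravity) frame; the global +Z axis opposes
gravity and the calibration cradle pose defines the identity attitude.
Only tilt is observable without a magnetometer; heading rests on gyro
integration alone, which is acceptable because the downstream gravity
correction depends only on tilt (the rotated blade-weight vector
Rᵀ(0,0,M_b) is invariant to yaw).

The filter is a gradient-descent IMU fusion with unit gain β = 1 (the
corrective-step magnitude in rad/s) at 200 Hz. Two deliberate
modifications relative to the classical normalised-gradient form:

* **Proportional correction.** The gravity-alignment gradient is applied
  *unnormalised*. The classical form normalises the gradient and applies
  a fixed-magnitude step β·Δt, which at β = 1 and 200 Hz is a 0.57°
  attitude step: near convergence the filter limit-cycles at that
  amplitude, and under steady sinusoidal motion the induced error grows
  to several degrees at 5 Hz. The proportional step (gradient magnitude
  ≈ 2ε for misalignment ε) vanishes at convergence, giving a tilt time
  constant of 1/(2β) = 0.5 s and measured steady-motion errors below
  0.05° at 0.5–5 Hz.
* **Predict, then correct.** The gradient is evaluated at the
  gyro-propagated quaternion rather than the previous estimate, removing
  a one-sample lag that otherwise grows linearly with motion frequency.

Numerical details: first-order quaternion integration with explicit
renormalisation each step (norm conserved to < 1e-9 over arbitrary
sequences); a zero-norm accelerometer sample skips the corrective step;
the pitch argument of the Euler conversion is clamped to ±1; Euler
angles are produced for reporting only — all internal composition uses
quaternions, so gimbal proximity affects nothing but the printed angles.
The initial attitude is the minimal tilt rotation aligning the mean
calibration-window accelerometer sample with +Z, refined by running the
filter over the calibration window; gyro biases are the per-axis means
of that window.

## Force calibration and gravity correction

Each 3-D load cell converts as `F = A·(V − V_off)` after a causal
25-sample rolling mean (partial window during warm-up, so there is no
startup transient). The measured no-load offsets `V_off` are per-channel
means over the calibration window; because the blade hangs from the
cells, those means contain the blade-tension shift ξ on the
gravity-aligned z channel in addition to the electronics zero. The shift
is estimated as the z-channel calibration mean minus the config-supplied
electronics zero, averaged over the two cells (shared-ξ model; a
per-cell override is possible by editing the offsets directly).

Subtracting the *measured* offsets removes the blade tension as a
constant, which is only correct in the calibration pose — rotated away
from it, the tension moves into the other axes ("orthogonal skewness").
The pipeline therefore applies the ξ correction with the sign that
*restores* the tension on z (`F_z += A₃₃·ξ`), so the calibrated combined
force is

    F₃D = F_applied + Rᵀ(0,0,M_b)ᵀ ,

i.e. the applied load plus the blade's weight as seen in the device
frame, at every orientation. The frame transformation then removes the
weight exactly where it belongs:

    F_corrected = Rᵀ(R·F₃D − (0,0,M_b)ᵀ) = F₃D − Rᵀ(0,0,M_b)ᵀ .

With this composition the residual after correction is pure measurement
noise: over 1,000 random attitudes with ADC-level channel noise the mean
per-axis residual measures ≈ 0.024 N, comfortably inside the 0.2 N
per-axis noise budget of the device class. Note the ξ correction only
touches the z row; with ~5 % matrix cross-talk the x/y leakage of the
tension voltage contributes ≲ 0.01 N, absorbed in that budget.

Parameters: blade weight M_b = 2.5 N; rolling window n = 25; saturation
clip ±325 N per axis; characterization matrices are device-specific and
supplied by configuration (the simulator's defaults put one 16-bit ADC
step of 0.025 mV at ≈ 0.1–0.2 N compressive, 0.05–0.1 N planar).

## Contact state machine and time ledger

Treatment mode has four states: calibration until the first button
press, then ready/operational split by the 1 N skin-contact threshold
(set well above the force noise floor), with pause toggled by button
presses from any non-calibration state. A 3-tick debounce (30 ms at
100 Hz) is applied to ready↔operational crossings to suppress chatter
near the threshold; button presses act on their rising edge. Contact
time counts operational ticks; ready plus pause time is dead time;
their sum is the elapsed treatment time (calibration is outside the
treatment clock). A sub-session is a maximal contact run between
pauses.

## Stroke detection

Smoothing defaults to the binomial kernel of window 25 — the 25
coefficients C(24, k)/2²⁴, an odd-length zero-phase kernel with
σ ≈ 2.45 samples (24.5 ms at 100 Hz). The window-26 reading of the
kernel definition (C(25, k)) was rejected because an even-length kernel
shifts the stream by half a sample. The alternative smoother is an
order-10 Butterworth at 11 Hz cutoff, applied forward-backward in
second-order sections (zero phase, numerically stable at high order).

Peaks and valleys are the sign changes of the first difference, with
plateaus assigned to their first sample and synthetic boundary valleys
at the segment ends; detection runs per sub-session segment. Each
valley→peak→next-valley triple gets a confidence ratio
(P−Vᵢ)/(P−Vᵢ₊₁); ratios outside the acceptance band mark redundant
peaks. The band is (0.33, 3.0) by default — the thresholds are a device
tuning constant with no published value; these were chosen (and
config-exposed) so that symmetric strokes (ratio ≈ 1) always pass while
shoulder ripples, whose rise or fall is a small fraction of the other
side, fail. A rejected peak is merged into the adjacent cycle: its
shallower flanking valley is deleted and the taller of the two merged
peaks survives, consistent with "one maximum peak per force-motion
cycle"; merging repeats (worst offender first, severity measured on a
log scale) until all surviving ratios sit in the band, which makes the
operation idempotent. A 1 N prominence floor (the contact threshold)
keeps noise wiggles in near-contactless segments out of the decision
tree entirely.

Stroke peak *amplitudes* are read from the unsmoothed resultant within
the detected valley-to-valley span: the smoothing that stabilises
detection attenuates fast crests (≈ 1 % at 3 Hz through the rolling
mean, ≈ 5 % at 2 Hz through the binomial kernel), and the cycle maximum
of the raw stream is the quantity of clinical interest.

Stroke frequency is reported two ways: count over elapsed treatment
time (canonical) and count over contact time; both appear in the
report. Bursts are greedy splits of the stroke train when an
inter-stroke interval exceeds 2 s, deviates more than 35 % from the
running burst mean, or crosses a sub-session boundary (both parameters
config-exposed; no published values exist). Burst pattern labels
(linear / curvilinear / hybrid) are a best-effort heuristic from the
spread of the planar-force direction and the yaw excursion — useful for
eyeballing treatment charts, not a validated classifier.

## Report

Averages are taken over operational ticks only (dose is undefined
off-skin); the compressive average uses |F_z|. The application angle is
defined as 90° minus the elevation of the blade's compressive (local z)
axis above the global horizontal plane — 0° with the device upright in
its calibration pose, growing as the compressive axis tilts toward the
treatment plane. The report is a pure function of its inputs.

## Synthetic device model

The simulator inverts the calibration chain exactly: scripted applied
force plus the rotating blade tension is split across the two cells
(50/50 by default, asymmetry configurable), pushed through the inverted
characterization matrices, offset, Gaussian-noise corrupted
(σ = 0.025 mV per channel by default) and snapped to the 0.025 mV ADC
grid. With noise disabled the chain is inverse-exact to < 1e-6 N at
every tick. IMU streams are analytic: accel is the body-frame gravity
direction, gyro the body rate at each sample interval's midpoint — the
output of a rate-integrating MEMS gyro — so integrating the stream
recovers the scripted trajectory to < 0.5° over a minute. Endpoint
sampling was rejected because it manufactures a half-sample integration
lag (~8 % of amplitude at 5 Hz) that real devices do not exhibit.

Strokes are half-sine resultant cycles riding on a 2.5 N contact
baseline (above the 1 N threshold, so sub-sessions are contiguous
skin-contact intervals as in real treatment charts), with a
pattern-dependent planar/compressive decomposition (35° planar angle;
alternating ±y for linear cross-fiber, rotating azimuth for curvilinear
fanning). Tissue-irregularity ripple is a narrow Gaussian bump on each
stroke's falling flank (centre 0.62 T, width 0.045 T) — the redundant-
peak generator; hand vibration is a small 9 Hz sinusoid enveloped by
the stroke. Sessions are framed by a 1.5 s calibration window and
button-press edges around scripted pauses; identical scripts and seeds
are bit-reproducible.

What the simulator does **not** model: soft-tissue mechanics and
friction, thermal drift over long sessions, load-cell saturation
physics beyond a hard clip, accelerometer corruption by linear
acceleration of the hand (accel is pure gravity direction plus noise),
and truly non-deterministic clinician motion. Passing validation
therefore demonstrates correctness of the processing chain against the
stated device model, not robustness to every clinical artefact; in
particular the stroke-count accuracies on scripted sessions are upper
bounds on what irregular human motion would yield.

## Validation problem sizes

The validation suite (shared by `scripts/acceptance.py`,
`qstm validate` and the acceptance tests) uses: 20 smooth sessions of
30 strokes (0.5–1.5 Hz, 10–40 N, ripple < 5 %) and 20 uneven-contour
sessions (±45° roll / ±25° pitch sweeps, 10–25 % crest ripple, pace
0.5–3 Hz within a session); 1,000 random attitudes at 0.5 s each for
the no-load residual; 60 s trains at 0.5–5.0 Hz for rate fidelity;
10,000 random-input filter updates for norm conservation; and 30 s
sinusoidal rotations at {0.5, 1, 2, 5} Hz, 30° amplitude, for tracking
error with the first 2 s of convergence discarded. Per-case seeds are
derived deterministically from the suite's base seed.

## Known limitations

* Heading drifts without a magnetometer; only tilt-dependent outputs
  (gravity correction, application angle) are drift-free by
  construction. Motion-path reconstruction relative to the body is out
  of scope.
* Burst identification for non-deterministic motion uses simple
  gap/pace segmentation; hybrid bursts with smoothly varying pace can
  split or merge.
* The confidence band, burst parameters and pattern-label thresholds
  are simulator-calibrated defaults, not clinically fitted constants.
* Streams with dropped samples are handled by holding the previous
  value, which biases the rolling mean for long dropouts.
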