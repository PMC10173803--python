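# qstm

Force-motion processing for handheld **quantifiable soft-tissue
manipulation (QSTM)** therapy devices.

Instrument-assisted soft-tissue manipulation is a force-based manual
therapy whose practice is still largely subjective: a clinician's
targeted force, application angle, stroke rate and motion pattern are
neither recorded nor reproducible. An instrumented handheld blade —
two 3-D load cells carrying a suspended treatment blade plus a 6-DOF
IMU — makes those quantities measurable. This package implements the
full signal chain that turns such a device's raw sample stream into
clinically meaningful treatment parameters, together with a synthetic
device simulator so the whole chain can be exercised and validated
without hardware.

## What it computes

Per 500 Hz raw frame (two load-cell voltage triples, accelerometer,
gyroscope, control button), the chain produces a 100 Hz processed
stream and session-level report:

1. **Attitude.** A modified gradient-descent AHRS filter fuses gyro and
   accelerometer at 200 Hz into a unit quaternion `q0 + q1·i + q2·j + q3·k`
   (β = 1); Euler angles ψ, θ, ∅ follow by the standard Z-Y-X conversion.
2. **Force calibration.** Offset-subtracted channel voltages are
   rolling-mean filtered (n = 25) and mapped to Newtons through the
   3×3 characterization matrices **A** of each cell, with a baseline-shift
   correction ξ on the gravity-aligned channel; the two cells sum to the
   device-frame force **F**₃D.
3. **Gravity correction.** The suspended blade's weight (M_b ≈ 2.5 N)
   contaminates every orientation. With R(ψ,θ,∅) = R_z·R_y·R_x,

       F_corrected = Rᵀ · ( R · F₃D − (0, 0, M_b)ᵀ )

   and the resultant ‖F_corrected‖ is the instantaneous **dose-load**.
4. **Contact tracking.** A four-state machine (calibration → ready ↔
   operational ↔ pause) classifies each tick by the 1 N skin-contact
   threshold and button toggles, yielding contact/dead/elapsed time.
5. **Stroke detection.** The resultant stream is smoothed (binomial
   kernel n = 25, or a zero-phase order-10 Butterworth at 11 Hz);
   peaks/valleys come from first-difference sign changes; redundant
   peaks (hand vibration, tissue irregularities) are discarded by
   thresholding the **confidence ratio** (P−Vᵢ)/(P−Vᵢ₊₁) of each
   valley-peak-valley triple, keeping one maximum peak per
   force-motion cycle.
6. **Report.** Average compressive/resultant force, max and mean
   (target) peak force, stroke/burst/sub-session counts, contact and
   elapsed time, stroke frequency, mean application angle.

## Worked example

Simulate a two-sub-session treatment (20 linear strokes at 2 Hz peaking
25 N, a 5 s pause, then 10 curvilinear fanning strokes at 1 Hz peaking
15 N) and process it back:

```bash
cat > script.yaml <<'YAML'
subsessions:
  - - {peak_force: 25.0, rate: 2.0, n_strokes: 20}
  - - {pattern: fanning_curvilinear, peak_force: 15.0, rate: 1.0, n_strokes: 10}
pause_duration: 5.0
YAML

qstm simulate --script script.yaml --seed 7 -o out/
qstm process out/raw.csv --cal out/cal.yaml -o report.json --strokes-csv strokes.csv
qstm report report.json
```

which prints:

```
schema_version            1
avg_compressive_force     10.557
avg_resultant_force       12.830
max_peak_force            24.951
target_force              21.597
n_strokes                 30
n_bursts                  2
n_subsessions             2
contact_time              21.520
elapsed_time              27.100
stroke_frequency          1.107
stroke_frequency_contact  1.394
avg_application_angle     0.014
```

All 30 scripted strokes are recovered in two bursts across the two
sub-sessions; the maximum peak reads the scripted 25 N to within the
sensor noise, the target force (mean of all stroke peaks, 20 × ~25 N and
10 × ~15 N) is ≈ 21.6 N, and the stroke frequency is the count over the
elapsed treatment time (30 / 27.1 s ≈ 1.11 Hz; 1.39 Hz over contact
time alone). The application angle is ~0° because the script kept the
device in its upright calibration pose.

The same chain is available as a library:

```python
from qstm import SessionScript, StrokeScript, simulate_session, run_session

script = SessionScript(subsessions=[[StrokeScript(peak_force=25, rate=2, n_strokes=20)]])
stream, truth = simulate_session(script)
result = run_session(stream, script.cal)
print(result.report.to_json())
```

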