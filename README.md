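# mmdtkit

Multi-sensor assessment of the **Minnesota Manual Dexterity Test (MMDT)**:
a Python library and CLI that scores the 60-disc pegboard test from three
synchronized streams and turns the measurements into clinical findings.

The MMDT is scored traditionally by a stopwatch and a supervisor. This
package automates and deepens that score:

* **Vision** — a fixed 640×480 camera watches the board; per-hole HSV
  colour thresholds (white = empty, red = disc face-up, black = flipped)
  and a debounced state machine time every disc placement and turn.
* **EMG** — an 8-channel forearm band at 200 Hz; envelopes (20 dB gain,
  rectification, 2nd-order 3 Hz Butterworth) feed a **log-linearized
  Gaussian mixture network (LLGMN)**, whose softmax over
  quadratic-expanded inputs `(1, x, x_i x_j)` realises a Gaussian-mixture
  posterior `P(y|x)`, classifying each sample as *hold* / *release* /
  *rest* and accumulating grasp time.
* **IMU** — gyro (°/s) and accelerometer (g → m/s², gravity-subtracted)
  summaries per phase: peak angular velocities, mean acceleration peaks,
  and inactivity ("thinking") time below configurable thresholds.
* **Expert rules** — conjunctive IF–THEN rules over the measurements
  (`IF tt_t > max_t_t AND rot_r_t < nrot_r_t THEN "Insufficient rotation
  in turning…"`) emit textual findings; the rulebase and thresholds are
  plain JSON and clinician-extensible.

Because no public dataset exists, `mmdtkit.synth` generates complete
synthetic sessions — board frames, EMG, IMU — from a ground-truth
schedule, and the published measurement tables of a 20-participant healthy
cohort are packaged as fixtures for the aggregate statistics.

Intended users: rehabilitation-engineering researchers and developers of
instrumented dexterity assessments.

## Worked example

Simulate a placing-phase session and analyze it:

```sh
mmdt simulate scratch/demo --phase placing --seed 5 --n-discs 12
mmdt analyze scratch/demo
```

which prints (numbers from this exact invocation):

```
MMDT session report (phase: placing)
  discs detected : 12 (placed 12, empty 48)
  total phase time: 12.30 s
  total hold time : 5.28 s
  max |angular velocity| (deg/s): roll 177.3, pitch 178.0, yaw 148.6
  mean accel peaks (m/s^2): x 1.80, y 1.74, z 1.76
  inactivity time : 8.66 s
  findings:
    (none)
```

Read: all 12 scheduled discs were detected (the ground-truth schedule in
`scratch/demo/schedule.json` ends at 12.27 s — the vision total of 12.30 s
is within one frame interval); the classifier attributes 5.28 s to grasping
(scheduled: 5.30 s); no rule fires because a 12-disc mini-session finishes
far below the 62 s placing limit. The full report is written to
`scratch/demo/report.json`.

The same pipeline is available as a library:

```python
from mmdtkit.session import simulate_session, analyze_session
report = analyze_session(simulate_session("scratch/demo2", seed=5))
```

`mmdt validate-tables` recomputes every packaged-table aggregate (hold-time
agreement accuracies, cohort means) and reports pass/fail per check.

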