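# Methods

`mmdtkit` automates scoring of the Minnesota Manual Dexterity Test (MMDT):
a 60-disc pegboard test with a *placing* phase (discs moved into holes
red-side up) and a *turning* phase (discs flipped red→black in place). The
system fuses three sensor streams — a fixed board camera, an 8-channel
forearm EMG band, and the band's IMU — and interprets the measurements with
a clinician-authored rulebase. This note describes the models, the
parameters that matter, the synthetic data the package validates against,
and the limits of both.

## EMG processing and the contraction level

Raw EMG (mV, 200 Hz, 8 channels) passes through an amplitude gain of 20 dB
(×10), full-wave rectification, and a causal 2nd-order low-pass Butterworth
with 3 Hz corner (bilinear design at fs = 200 Hz, unity DC gain). The
filter is applied single-pass because the system targets real-time use;
its ~75 ms group delay therefore shifts every envelope feature slightly
rightward, which is visible in all downstream timing comparisons. Envelope
ringing can dip below zero; the output is clipped at 0 since an envelope is
a magnitude.

Two normalisations feed classification:

* the **channel-share vector** `(e_i − r_i) / Σ_j (e_j − r_j)` (components
  sum to 1), where `r` is the per-channel rest envelope — this is the
  classifier input;
* the **muscle contraction level (MCL)**, the channel-mean of
  `(e − r)/(m − r)` with `m` the maximal-contraction envelope — a scalar
  ≈[0, 1] used only to gate rest from motion (default gate 0.05, clamp
  [0, 1.5] to tolerate supra-calibration squeezes).

The share vector is undefined at rest (zero denominator), which is why the
MCL gate runs first. Calibration (`rest`, `max` per channel) comes from a
relaxed recording and a vigorous disc squeeze.

Training data come from 8-s gesture recordings with the gesture performed
between seconds 2 and 6; 20 share vectors are sampled evenly from that
window (a seeded random subsample is available). Window features
(MAV = mean |x|, IEMG = Σ|x|, RMS) are provided for benchmarking other
classifiers but are not used by the shipped pipeline.

## The LLGMN classifier

The log-linearized Gaussian mixture network represents a Gaussian-mixture
Bayes classifier as a log-linear model: inputs are expanded to
`(1, x, {x_i x_j}_{i≤j})` (length 1 + D + D(D+1)/2; 45 for D = 8), each
(class, component) pair owns one weight vector over the expanded features,
a global softmax normalises all pairs, and a class posterior is the sum of
its components' mass. Because the log of a Gaussian density is a quadratic
form, a known single-Gaussian-per-class model maps *exactly* onto weights
(`gaussian_bayes_weights`), giving an analytic bridge to a brute-force
density oracle that the tests exploit.

Training maximises conditional log-likelihood by full-batch gradient
ascent (lr 0.05, ≤500 epochs, stop when |Δ log-likelihood| < 1e−8, seeded
small-random init, one weight set pinned at zero for identifiability).
Inputs are z-scored on training statistics by default; the transform is
stored in the model and applied at inference. This conditioning matters:
with only 20 samples per class the 45-dimensional quadratic expansion of
raw-scale inputs generalises poorly, while standardized inputs recover the
Bayes boundary on well-separated classes. Components per class default to
K = 1; the hold/release discrimination is close to unimodal per gesture.

Stream segmentation labels every sample hold / release / rest: rest when
MCL < gate, otherwise argmax posterior with ties at 0.5 broken toward
release (ambiguity must not accrue hold time), followed by a width-5
median filter to remove single-sample flicker. Total hold time is the
hold-label count × dt.

## Board vision

Frames are 640×480 RGB. Only pixels near the 60 known hole centres are
inspected (default layout: 4×15 grid, centres ≥ 30 px apart, sampling disc
radius 5 px). Colour classification is a threshold test in HSV with hue on
the half-degree 0–180 scale (S, V on 0–255):

| class | H | S | V |
|---|---|---|---|
| white | 0–180 | 0–30 | 220–255 |
| red | 0–10 ∪ 160–180 | 100–255 | 30–255 |
| black | 0–180 | 0–255 | 0–30 |

The ranges overlap (a very dark red satisfies both red and black);
precedence black → red → white resolves this — darkness dominates, which
matches the observed failure mode of shadowed discs reading as black. A
hole's class is the majority vote over its sampling disc; ties and
out-of-range pixels give `unknown`, which never drives an event (fail-safe
under shadows and flashes).

A per-hole state machine converts class transitions into timed events —
placing: white→red `placed_correct`, white→black `placed_upside_down`;
turning: red→black `turned_correct`, red→white `removed_incorrect`. A
transition must persist for 2 consecutive frames (debounce) and is stamped
with the first frame's time. The turning phase initialises every hole red
(the board is full after placing). Per-disc durations are gaps between
consecutive events (first relative to phase start), so durations sum to
the total phase time by construction.

## IMU kinematics

Gyro (roll/pitch/yaw, °/s, ±2000) and accelerometer (g, ±16) traces are
sampled at 50 Hz (configurable). Acceleration converts to m/s² with 9.81
subtracted from Z only — the sensor Z axis is assumed near world-vertical;
no orientation fusion is attempted, a deliberate physical simplification.
Phase summaries report max |angular velocity| per axis (the signed-versus-
magnitude choice is ambiguous in common reporting; we use magnitude) and
the mean of local |acceleration| peaks per axis (scipy peak detection,
prominence ≥ 0.3 m/s²; 0 when no peaks). Inactivity ("thinking time") is
the total duration of samples with every gyro axis < 10 °/s **and** every
gravity-compensated accel axis < 0.3 m/s²; both thresholds are exposed in
configuration because no published values exist.

## Expert rulebase

Rules are conjunctions (optionally disjunctions) of comparisons between
measurement variables (`tt_p`, `tt_t` phase totals; `rot_*`, `acc_*`
kinematic summaries; `th_*` inactivity; `d{i}_*` per-disc times) and named
thresholds. Branch rules gate sub-rules: the acceleration check runs only
when placing exceeded its time limit, the roll-rotation check only when
turning did. The shipped rulebase carries the five published example rules
verbatim plus a per-disc delay family instantiated for all 60 discs of
each phase. Threshold defaults: upper phase limits 62 s (placing) / 67 s
(turning); lower limits 30 s placeholders (no published value); kinematic
minima are mean − 2·SD over the packaged 20-participant healthy-cohort
tables, floored at 0 (a stated convention for "the normal range");
inactivity 10 s and per-disc 3 s placeholders. "Normal" is suppressed when
any abnormal finding fires — the rule structure implies exclusivity
without stating it. Findings keep machine ids alongside the clinical
texts; evaluation is a pure function of (context, thresholds, rulebase).

## Agreement metrics and rounding

Two percent-difference conventions are deliberately distinct operations:
`time_error` uses the manual stopwatch reference as denominator
(E_T = |T_s − T_m|/T_m·100); `holdtime_difference` uses the classifier
hold time as denominator — the convention under which the published
hold-time comparison column reproduces digit-for-digit (e.g. 1.2/31.6 →
3.8%). Report rounding is half-away-from-zero at the printed precision,
computed in exact decimal (Fraction) arithmetic because several cohort
means land exactly on .x5 ties (27.45 → 27.5, 61.65 → 61.7) where binary
floating point or banker's rounding would disagree. Standard deviations
are sample (n−1); on the packaged tables population and sample std round
identically, so the choice is recorded rather than inferable.

## Synthetic sessions

No public dataset exists, so `synth` generates complete sessions from an
explicit schedule that doubles as ground truth.

* **Board frames** — white board (RGB 240) with discs (radius 12 px)
  rendered red (100, 12, 12) or black (12, 12, 12), ±3 counts of seeded
  uniform noise per channel, 10 fps default. The red face is deliberately
  dark (V ≈ 100) so the shadow perturbation (local luminance ×0.25)
  drives it below the black threshold, reproducing the real shadow
  failure mode; flash sets a local patch to saturation 0 / value 255
  (reads white), dim halves the global value (discs remain classifiable;
  empty holes read `unknown`, which is fail-safe).
* **EMG** — channel envelopes follow rest plus trapezoidal activations:
  grasping drives channels 4–5 to ≈1.15× the calibrated span (in-test
  squeezes exceed the calibration squeeze, keeping MCL clearly above the
  gate) with ≤30 % co-activation elsewhere; the open-hand gesture has a
  distinct mix. The release gesture spans the whole inter-disc interval —
  the hand reaches for the next disc open — so both label boundaries are
  classifier crossovers with symmetric delays and the accumulated hold
  time is unbiased despite the causal filter lag. The envelope (Gaussian
  noise σ = 2 % of span, clipped at 0) is divided by the gain and
  modulated onto a ±1 rectangular carrier, so the preprocessing chain
  recovers it exactly.
* **IMU** — half-sine bursts over a gravity baseline with datasheet RMS
  noise (0.06 °/s, 4 mg). Per reach, co-located gyro (140–180 °/s) and
  accel (1.2–2.0 m/s²) bursts: these amplitude ranges make the accel
  above-threshold interval nest strictly inside the gyro one, so quiet
  boundaries are set by the steep gyro edges and the noiseless
  realization of the same schedule recovers every quiet-interval duration
  to within one sample.

What the generator does **not** emulate: hands and occlusion, motion blur,
biophysical EMG statistics (it is an envelope model on a carrier), sensor
drift or orientation change. Passing tests therefore demonstrate the
correctness of the measurement and inference chain under the stated signal
model, not camera-and-skin-level robustness; the published detection
accuracies under manipulated lighting depend on the physical rig and are
replaced here by the containment property (misdetections occur only at
perturbed holes).

## Validation studies and problem sizes

`mmdtkit.validation` backs the acceptance checks: (i) 50 seeded
normal-light sessions of 60 events each, alternating phases, must be
detected 100 % with correct kinds (inter-event gap ~0.35 s here — a
problem-size choice for the study; the generator's realistic default is
~1 s, matching published per-disc times, and detection only requires the
gap to exceed the 2-frame debounce); (ii) shadow/flash sessions must
confine colour misdetections to perturbed holes; (iii) the classifier
trained on 20 samples/class from two 8-D unit Gaussians offset 4σ per
coordinate must reach ≥95 % held-out accuracy, and analytically
constructed weights must match the brute-force Bayes oracle to <1e−6;
(iv) one full session must be recovered end-to-end: per-disc durations
within one frame interval, total hold time within 2·dt per transition,
quiet-interval durations within one IMU sample.

## Known limitations

* Hold-time accuracy degrades for gestures shorter than a few filter time
  constants (~0.3 s); the envelope lag is physical, not removable causally.
* Gravity compensation ignores arm orientation; sustained tilted postures
  bias the Z acceleration.
* Dropped discs are not detected (out of scope; known limitation of the
  original system).
* The lower phase-time limits, inactivity and per-disc thresholds are
  placeholders pending clinical calibration; the shipped config flags them.
* Board geometry is fixed 4×15 with manually specified hole centres; no
  automatic calibration from imagery.
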