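# Methods

## The separation problem

A body-worn tri-axial accelerometer measures specific force: movement
acceleration plus the reaction to the 1 g gravitational field projected
onto the sensor axes, plus noise. Summarising "how much movement" from
the raw signal therefore requires removing the gravitational component.
Two families of assumptions exist:

* **magnitude-based** (ENMO): gravity contributes exactly 1 g to the
  vector magnitude, so `EN - 1` is movement;
* **frequency-based** (HFEN, BFEN): gravity lives below a cut-off
  frequency (0.2 Hz by default), so per-axis high-pass filtering
  removes it.

Both fail during rotation in the vertical plane: the gravity projection
then oscillates *at the rotation frequency*, overlapping the movement
band, while the vector-magnitude assumption breaks because movement and
gravity are not collinear. HFEN+ is the hybrid: `HFEN + (LFEN - 1)`,
where LFEN (the norm of the low-pass-filtered axes) measures how much
magnitude the low band actually holds. When rotation pushes gravity
above the cut-off, LFEN drops below 1 g and the correction subtracts
the leaked gravity from HFEN; sustained low-frequency accelerations
(e.g. centripetal force on a swing) push LFEN above 1 g and are added
back.

All metrics are per-sample series in g. Negative values (possible for
ENMO and HFEN+) are clamped to zero for free-living human processing
and kept signed on the kinematics bench, where the sign is the
diagnostic. For HFEN+ the clamp applies to the summed series, not per
term, because the metric is defined as the sum.

## Kinematics bench

The bench emulates a robot arm oscillating a bar of accelerometers in
the vertical plane. Each half-period sweep between the angle bounds is
the unique degree-7 polynomial with zero velocity, acceleration and
jerk at both ends,

    s(tau) = 35 tau^4 - 84 tau^5 + 70 tau^6 - 20 tau^7,

which minimises the vibration transmitted to the rig; angle, angular
velocity and angular acceleration come from the analytic derivatives,
never from numerical differentiation. "Frequency" counts full
back-and-forth cycles per second, consistent with a one-cycle-per-
second condition sweeping up and back down within one second.

The movement acceleration of a sensor at radius `r` is the vector sum
of the tangential component `r*alpha` and the centripetal component
`r*omega^2`; its magnitude (in g) is the forward-kinematics reference.

The simulated sensor signal places the tangential term plus
`cos(theta)` of gravity on the in-plane axis perpendicular to the bar,
and `sin(theta) - r*omega^2/9.81` on the axis parallel to the bar
(pointing away from the rotation axis). The relative sign on the
parallel axis is physical, not conventional: the centripetal
acceleration points toward the axis while the gravity reaction reads
positive when the bar is above horizontal, so the two terms oppose.
This is observable in every norm-based metric — it is what pulls LFEN
below 1 g during vertical-plane rotation and makes the HFEN+
correction negative, matching the error structure recorded on the
physical rig. (A whole-axis sign flip, by contrast, is invisible to
norms and remains a free convention.) Optional white Gaussian noise
per axis emulates the 2.6 mg sensor noise floor; structured rig
vibration is not modelled.

The condition grid comprises 37 moving frequencies (0.05–0.55 Hz in
0.05 steps over 0–90°; 0.6–0.8 Hz over 0–45°; 0.9–1.1 Hz over 0–20°;
1.2–1.3 Hz over 0–45°; 1.4–2.6 Hz in 0.1 steps plus 2.8, 3.0, 3.2,
3.6, 4.0 Hz over 0–20°) plus two static holds (0° and 22.5°). Sensor
radii: 18 positions for frequencies up to 1.1 Hz and 5 positions above,
spaced **evenly** over 0.13–0.78 m and 0.13–0.29 m respectively. Only
the spans of the physical layouts are documented, so even spacing is a
declared assumption and every band-averaged comparison inherits it.

## Evaluation protocol

Each (condition, radius, metric) is summarised by the mean over the
largest whole number of oscillation periods that fits inside the middle
two minutes of the 3-min recording, anchored at t = 30 s. The integer-
period rule makes the mean of any zero-mean oscillation vanish exactly;
the excluded first 30 s absorb the causal filter transient. Errors are
`estimate - reference` in mg and, when the reference is non-zero,
`(estimate - reference)/reference` in percent; static rows report mg
only. Band summaries group cells by frequency band, angle range and
radius band (0.1–0.3, 0.3–0.6, 0.6–0.8 m), averaging relative errors
per condition first and then across the cell.

## Filter application

Filters are 4th-order Butterworth (SciPy second-order sections).  The
default application is a **causal single pass** from zero initial
conditions. The choice matters because the norms are nonlinear:
forward-backward (zero-phase) filtering squares the magnitude response,
which changes how much near-cut-off gravity leaks into the high band.
The causal default reproduces the error structure recorded on the
physical rig distinctly better than the zero-phase alternative (e.g.
for the 0.25–0.55 Hz / 0.6–0.8 m band the causal simulation gives
HFEN ≈ 291 mg and HFEN+ ≈ −4 mg, against ≈ 380 mg and +78 mg for
zero-phase), and matches the convention of the R signal-processing
stack in which such pipelines are typically built. Zero-phase
application remains available (`zero_phase=True` everywhere, and
`filter.zero_phase` in configs) for users who prefer no phase
distortion. Group delay is irrelevant to period-averaged magnitudes.

Filter transients are not trimmed inside the metric functions; the
bench window excludes them, and at day scale they are negligible.

## Free-living chain

* **Calibration**: per-axis offset and gain fitted by least squares so
  static points (mean vectors of motionless recordings) have unit
  magnitude. At least six orientations spanning both signs of every
  axis are required; the fit is rejected if any calibrated point
  deviates from 1 g by more than 3 mg, or if the parameters stray
  implausibly far from identity (|gain−1| or |offset| above 0.1).
* **Clipping**: a 15-min clock-aligned block is flagged when more than
  1% of its samples reach 99% of the ±6 g dynamic range.
* **Non-wear**: a 60-min sliding window stepping one block flags its
  blocks when at least 2 axes have sample SD below 13 mg. This rule is
  a configurable stand-in in the style of established raw-accelerometry
  pipelines (the original study's exact criteria live in material not
  available here); all four parameters are keywords.
* **Epoching**: per-sample metric values averaged over non-overlapping
  60-s epochs; a trailing partial epoch is dropped.
* **Imputation**: flagged blocks are replaced epoch-slot-wise by the
  mean of the same clock-time blocks on unflagged days; when a block is
  flagged on every day the fill is 1 g for EN and 0 g for all other
  metrics (a motionless sensor still reads gravity, so EN's neutral
  value is 1). The operation is idempotent because donors are always
  unflagged days.
* **Inclusion**: strictly more than 50% overall wear time and at least
  one valid day (its own wear fraction above 0.5). Exactly 50% wear is
  excluded.

## Synthetic cohort

The generator scripts each day as activity bouts (band-limited
0.3–5 Hz oscillation riding along the instantaneous gravity direction,
raised-cosine on/off ramps), non-wear intervals (exactly static), and a
slow orientation drift (sinusoids with ~30–90 min periods, amplitude
10° wrist / 4° hip), plus the 2.6 mg noise floor. Bout frequencies are
kept above 0.3 Hz so the 0.2 Hz cut-off separates drift from movement
cleanly in this synthetic world; a dedicated slow-rotation scenario
(0.05–0.15 Hz orientation sweeps) exercises the opposite regime, where
frequency-filtered metrics report spurious movement and ENMO does not.

Movement along gravity of amplitude `A` yields truncated ENMO of
`A/pi` while active, which ties a participant's bout script to a target
daily activity volume (drawn as N(32, 10) mg across participants,
floored at 5). True energy expenditure follows an explicit linear
model, `PAEE = -0.172 + 0.025*BW + 0.057*volume + N(0, 0.94)` MJ/day
with body weight ~ N(65, 10) kg — the shape and scale of published
wrist-accelerometry models — so the regression layer has exact
coefficients to recover. Hip recordings share the wrist bout script
with 0.7× participation, smaller drift and a nightly non-wear block.

What the synthetic world does **not** contain: gait harmonics and heel-
strike impacts, posture transitions, multi-axis movement textures,
autocorrelated measurement error, or device artefacts. Tests passing
on this cohort therefore demonstrate correctness of the processing and
statistics chain under its stated assumptions, not field validity of
any metric on real human data.

## Cohort statistics

The within/between decomposition of a metric pair is estimated as the
squared correlation of participant-mean-centred epoch values (within)
and of participant means (between). The estimator is symmetric in the
pair, invariant to linear maps of either metric, invariant to epoch
reordering (between) and per-participant offsets (within). The original
repeated-measures ANOVA is not specified in enough detail to reproduce
exactly; this decomposition realises the same construct in a testable
form. PAEE models are ordinary least squares of PAEE (MJ/day) on body
weight and one per-person metric summary (mg); additive value of a
second metric is the nested-model F-test, with numerically collinear
additions reported as zero gain.

## Problem sizes and numerical choices

* Bench runs use the full grid at 80 Hz, 3 min per condition (406
  condition-radius pairs) — a few seconds of compute; the reduced
  `mini` grid covers one condition per regime for smoke tests.
* Cohort examples and tests run at 20 Hz with shortened days (2–4 h)
  and 6–20 participants; the statistics suites (coverage, null
  calibration, power) draw summaries directly from the generating
  model with 100–200 replicates at n = 63. These sizes are the
  package's choices for fast, deterministic test runs; all are plain
  parameters.
* Derivative cross-checks compare the analytic kinematics against
  centred finite differences at a refined step (2×10⁻⁵ s), because the
  truncation error of finite differences at the 80 Hz sampling step is
  orders of magnitude above the agreement being asserted.
* Sampling frequency inferred from file timestamps is snapped to the
  nearest integer when within one part in 10⁶, so whole-sample checks
  downstream are not defeated by float round-off.
* Seeds are explicit and mandatory wherever randomness exists; noisy
  simulations without a seed raise immediately.

## Known limitations

* The even radius spacing and the exact in-plane axis conventions are
  declared reconstructions of a physical rig; band means inherit them.
* Rig vibration is modelled only as optional white noise, so simulated
  errors for bands where the physical rig's vibration floor dominates
  (a few mg to ~16 mg) sit systematically below the empirically
  recorded ones.
* The non-wear rule is a stand-in; sleep detection, bout
  classification and intensity cut-points are out of scope.
* Day stacking uses local clock time with fixed offsets;
  daylight-saving shifts are not handled.
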