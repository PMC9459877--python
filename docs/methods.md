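# Methods

This note documents the models, estimators and numerical choices behind
`clothgait`, in enough detail to reproduce or modify any stage.

## Coordinate conventions

The anatomical world frame is NWU-like: x anterior, y to the subject's left,
z up. Segment-to-vertical angles (SVA) are sagittal tilts in degrees,
**negative when the segment is inclined** (top leaning forward) and
**positive when reclined**. With this sign and frame, the physical
medial-lateral gyroscope component about +y equals −dθ/dt; the pipeline's
`omega` channel is therefore the *negated* aligned y gyroscope — the
rotation rate about the rightward medial-lateral axis — so that
ω = dθ/dt, the forward swing is a positive ω peak, and IC/TO appear as
local minima, matching how shank gyroscope traces are conventionally read.
A 180° yaw ambiguity is inherent to single-sensor alignment (flipping both
horizontal axes negates every horizontal channel and preserves all second
moments); it is resolved by the one robust asymmetry of human walking, that
the fastest sagittal rotation is the forward (reclining) swing, detected as
the sign of the skewness of the ML gyroscope over walking data. When the
gyroscope is essentially unexcited (below 10 deg/s), the sign falls back to
the largest-magnitude horizontal-acceleration sample.

Quaternions are scalar-first and map sensor-frame vectors into the world
frame. The SVA formula θ = arccos(2q0q2 + 2q1q3) − 90° is, exactly, the
angle between the *inverse*-rotated x-axis and vertical minus 90°; for the
planar (sagittal) rotations that dominate gait it equals the signed
elevation of the sensor x-axis above horizontal. The arccos argument is
clamped to [−1, 1]; successive quaternions are kept sign-continuous. The
z-axis angle θz = arccos(q0²−q1²−q2²+q3²) is computed for reference but not
used for gait, since it cannot distinguish leaning forward from backward.

## Alignment

* **Gravity rotation** — Rodrigues rotation about the axis perpendicular to
  the mean standing acceleration and +z, by the angle between them.
  Preconditions: ≥ 2 s of standing; mean magnitude within [0.8, 1.2] g
  (quasi-static check, rejecting mislabelled segments); antiparallel means
  (> 179°) are an error rather than an arbitrary axis choice.
* **Gyroscope bias** — the mean standing gyroscope is subtracted from the
  whole record (true rate is zero while standing). The first and last 2 s
  of the standing segment are trimmed (capped at 25% of the segment) so
  activity-transition motion cannot contaminate either static estimate.
* **Sagittal rotation** — first principal axis of the zero-meaned
  horizontal acceleration over all labelled dynamic segments pooled with
  equal sample weight (sit-to-stand, leg raises, walking), rotated onto +x;
  sign as above, anchored on the walking segment. Requires horizontal
  variance ≥ 1e−4 g².
* **Filtering** — zero-phase (forward-backward) 2nd-order Butterworth,
  3 Hz cutoff, odd-reflection edge padding, applied after alignment (the
  two operations commute; the order is fixed for reproducibility). DC gain
  is exactly 1.

## Orientation estimation

The IMU (magnetometer-free) Madgwick filter, with four departures from the
textbook update, each load-bearing at 50 Hz on gait-like signals:

1. **Trapezoidal gyro integration.** The quaternion step uses the
   quaternion exponential of the mean of consecutive body rates. A
   rectangle-rule step (rate at the current sample) carries an
   instantaneous error of (dt/2)·ω — about 3.6° at a 360 deg/s mid-swing —
   which dominates every other error source.
2. **Quasi-static weighting of the accelerometer correction.** During
   swing the accelerometer measures gravity plus large lever-arm
   accelerations; an ungated correction drags the attitude several degrees
   within each cycle. The correction is scaled by a smooth taper that
   vanishes when |‖a‖ − 1 g| exceeds 0.1 g or the angular speed exceeds
   60 deg/s. Both conditions are needed — magnitude alone is fooled when
   gravity plus a kinematic acceleration happens to cross 1 g mid-swing —
   and the taper is continuous so nearly identical streams receive nearly
   identical corrections.
3. **Proportional small-error correction.** The classical normalized
   gradient step has constant size β·dt regardless of the residual, so the
   filter never settles closer than that and jitters in a limit cycle. The
   step is scaled by min(1, ‖f‖/0.1): slew-limited (β rad/s) for large
   errors, exponentially convergent (time constant ≈ 0.1/β s) below ~6° of
   gravity mismatch.
4. **Gain β = 0.1** (the widely used default), with initialization from
   the first accelerometer sample. With bias calibration and the
   quasi-static weighting, accuracy is insensitive to β over 0.05–0.2;
   smaller gains under-correct slow residual drift.

Zero-norm accelerometer samples produce a gyro-only step with a warning.

**What "recovery" means.** The study design low-passes *all* channels at
3 Hz before orientation, and realistic shank kinematics carry genuine
content above 3 Hz, so the quantity this pipeline estimates is the
band-limited segment angle. Against the 3-Hz-filtered true angle the
pipeline recovers the shank SVA to ≈ 0.7° RMS noise-free (≈ 1.0° at default
sensor noise); against the raw angle the floor is ≈ 2° RMS for *any*
implementation of the filter-first design (pure integration of the filtered
gyroscope already shows it). Tests and acceptance checks therefore compare
against the band-limited angle.

## Gait-cycle extraction

* **Mid-swing:** peaks of the filtered acceleration magnitude above
  2.0 g (clothing) / 1.8 g (body), greedily keeping the largest peak within
  any 1 s window (one MS per stride at normal cadence). The magnitude peak
  localizes MS only to ±3 samples — its centripetal peak is flanked by
  lever-arm tangential lobes of comparable size — so each retained peak is
  refined to the maximum of the raw sagittal angular velocity within
  0.12 s; peak angular velocity is the defining property of mid-swing.
* **Cycles:** fixed length = rounded mean MS-to-MS gap, one cycle per MS
  whose window fits in the record; windows may overlap or leave gaps where
  strides deviate from the mean — the accepted cost of avoiding time
  normalisation. Truncated trailing cycles are dropped, not padded.
* **IC/TO:** first and last local minima of the shank ω inside the window
  with prominence ≥ 30 deg/s, refined on the raw (unfiltered) ω within
  0.08 s — the 3 Hz filter smears the large swing peak into the TO dip and
  otherwise biases it ~2 samples early. Cycles missing either event are
  flagged and excluded from statistics, never raised as errors.
* An optional correlation-to-mean outlier screen per cycle exists in the
  configuration and is off by default.

With the default generator, ≥ 95% (measured: 100% over 20 sessions) of
ground-truth MS/IC/TO events are recovered within ±2 samples, and the
detected stance share averages 59.3% against the constructed 60%.

## Pair comparison

Both streams of a clothing/body pair are cut with the **body**-shank-derived
cycle set (the body detector is the more reliable reference; the
clothing-derived set is still computed and reported). Per unflagged cycle a
standard Pearson coefficient; zero-variance cycles are excluded with a
warning. A Shapiro–Wilk normality screen on the per-cycle coefficients is
reported but never blocks computation. Angle differences
(clothing − body) are evaluated per sample over the trimmed standing window
(up to 2 min), per cycle at IC, and per cycle at the first zero crossing of
the body-shank SVA within [IC, TO] (nearest sample, no interpolation —
sample-level precision is appropriate at 50 Hz); cycles without a stance
crossing are skipped. Outlying correlations are reported, never removed.

## Synthetic-session generator

**Walking templates.** Each segment's angular-velocity cycle shape is a
periodic mixture of von-Mises bumps exp(κ(cos 2π(u−c) − 1)) on gait phase
u ∈ [0, 1): a broad positive swing bump centred exactly at MS, sharp
negative dips exactly at IC (phase (1−stance)/2) and TO (IC + stance), and
a wide shallow stance valley; the waist instead carries a two-bumps-per-
stride pelvis wobble. The angle is the exact primitive (zero cycle mean),
normalized to the configured amplitude and anchored at zero at MS (the
segment passes vertical near mid-swing — which also pins the acceleration-
magnitude peak to MS exactly). Event extrema are therefore at the
ground-truth times *by construction*, the swing peak is the global |ω|
maximum, and stance span equals stance_fraction × cycle duration exactly.
Cycle-to-cycle variability multiplies each cycle's duration and rate
amplitude by independent Gaussian factors (2% SD by default), with
amplitudes applied to the rate so the angle stays continuous across cycle
boundaries. Defaults: 1.2 s stride, 60% stance, amplitudes 34/22/3.5° for
shank/thigh/waist — ordinary self-paced adult walking.

**Protocol.** The default session mirrors the study protocol: ~2 min each
of standing, sitting, five sit-to-stand repetitions and five leg raises,
then a walking bout whose length is set by the requested cycle count.
Poses between activities are joined by 1.5 s smoothstep cross-fades that
occupy the tail of the preceding segment; walking starts and ends at early
stance, where the shank rate template crosses zero.

**Forward IMU model.** Each segment is a rigid pendulum: the accelerometer
senses (r·θ̈/g + sin θ, 0, r·θ̇²/g + cos θ) in the segment frame — gravity
exactly 1 g when static — with lever arms 0.55/0.18/0.08 m for
shank/thigh/waist (the shank value is an *effective* radius reflecting that
swing rotates the shank about hip and knee together; it yields mid-swing
magnitude peaks of 2.5–3 g after filtering, as needed for the 1.8/2.0 g
detection thresholds and consistent with real shank data). The gyroscope
reads the exact analytic rate. Both are rotated by the inverse of a random
per-sensor mounting rotation (uniform axis, angle up to 60°), then white
noise (0.02 g, 0.5 deg/s) and a constant per-axis gyro bias (uniform within
±0.5 deg/s) are added.

**Fabric model.** The clothing angle obeys
θc″ = −k(θc − g·θb) − c·θc′ plus band-limited angle noise (white noise
low-passed at the fabric's natural frequency and rescaled to `noise_sd`).
Integration is exact matrix-exponential propagation with cubic-Hermite
reconstruction of the driving angle between samples (the generator's
analytic rates supply the node derivatives) — fixed-step, deterministic and
unconditionally stable at any stiffness; a first-order-hold input would
leave a spurious half-sample lag in the rate channel that is visible in the
rigid limit. Defaults, calibrated once to everyday loose trousers and the
qualitative behaviour reported for them (wider clothing angle range,
preserved cycle shape, waist agreeing least):

| placement   | stiffness (1/s²) | damping (1/s) | gain | noise_sd (°) |
|-------------|------------------|---------------|------|--------------|
| waist       | 400              | 14            | 1.15 | 0.8          |
| thigh       | 600              | 20            | 1.10 | 0.5          |
| lower shank | 2500             | 45            | 1.06 | 0.3          |

i.e. natural frequencies ≈ 3.2/3.9/8 Hz at damping ratios 0.35–0.45. These
produce pooled mean per-cycle correlations of ≈ 0.87 (waist) and ≈ 0.98
(thigh, shank) through the full pipeline — the characteristic
waist-weakest ordering, comfortably above the agreement levels reported for
real loose clothing.

**What the generator does not model.** Planar (sagittal) kinematics only —
no frontal/transverse motion, no turning bouts, no foot-contact force
transients beyond the template dips, no soft-tissue artifact beyond the
linear fabric model, no magnetometer. Passing tests demonstrate that the
pipeline's machinery is correct and self-consistent under these idealized
conditions; they do not certify accuracy on real recordings, where fabric
behaviour is nonlinear, events are less stereotyped and turning produces
false mid-swing candidates (the flag-and-exclude mechanism and the optional
outlier screen are the designed mitigations).

## Problem sizes and determinism

The shipped tests use 20-cycle sessions with shortened static segments;
the acceptance script uses 50-cycle sessions (20 seeds for event/stance
statistics with a shank-only sensor set, 10 full six-sensor seeds for the
agreement statistics) — enough that the pooled estimates are stable to well
inside the tolerances checked. Every stochastic quantity derives from a
single seed via `numpy` SeedSequence spawning: identical seeds give
bitwise-identical sessions, and the analysis pipeline itself is fully
deterministic.
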