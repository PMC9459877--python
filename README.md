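# clothgait

Gait analysis with inertial sensors mounted in everyday loose clothing,
validated against body-mounted references.

Sensors sewn or taped into ordinary trousers would make long-term gait
monitoring far more comfortable than strapping IMUs to the skin — but fabric
moves relative to the limb, so the question is how much gait information
survives. `clothgait` implements the complete analysis pipeline for that
question: it aligns arbitrarily mounted 6-axis IMUs (50 Hz accelerometer +
gyroscope) to the anatomy, estimates per-sample orientation, computes
sensor-to-vertical angles, cuts walking data into gait cycles from
lower-shank signatures, and quantifies the agreement between each
clothing/body sensor pair. Because no public recordings of this kind exist,
the package ships a first-class synthetic-session generator with full ground
truth (true segment angles, true gait events, true mounting rotations), so
every stage is testable end to end.

It is aimed at wearable-sensing and movement-science researchers who want a
tested, reproducible reference implementation of this pipeline, or a
simulation harness for designing clothing-mounted sensing studies.

## Method

For each sensor (waist, thigh, lower shank; body- and clothing-mounted):

1. **Alignment.** A standing segment gives the gravity rotation (Rodrigues'
   formula, mapping the mean standing acceleration onto +z) and a static
   gyroscope-bias estimate; sagittal-plane movements (sit-to-stand, leg
   raises, walking) give a yaw rotation about z that maps the principal
   horizontal acceleration direction onto the anterior x-axis, with the
   anterior *sign* resolved from the forward-swing asymmetry of the
   medial-lateral gyroscope. All channels are then low-pass filtered with a
   zero-phase 2nd-order Butterworth at 3 Hz.
2. **Orientation.** A Madgwick-type IMU filter fuses gyroscope integration
   (trapezoidal quaternion-exponential steps) with a gradient-descent
   correction toward the accelerometer's gravity direction, the correction
   smoothly confined to quasi-static samples. The sensor-to-vertical angle
   follows from the scalar-first quaternion *q* as

       theta = arccos(2 q0 q2 + 2 q1 q3) − 90°,

   the tilt of the sensor x-axis from horizontal — negative when the segment
   is inclined (leaning forward), positive when reclined. The sagittal
   angular velocity omega is the medial-lateral gyroscope channel
   (d theta / dt).
3. **Gait cycles.** Mid-swing (MS) instants are peaks of the lower-shank
   acceleration magnitude above 1.8 g (body) / 2.0 g (clothing), one per 1 s
   window; cycles run MS-to-MS with one fixed length (the rounded mean
   MS gap). Initial contact (IC) and toe-off (TO) are the first and last
   prominent minima of the shank omega inside each cycle. Waist and thigh
   streams are cut with the same windows.
4. **Pair agreement.** Per cycle, the Pearson correlation between the
   clothing and body SVA traces; plus clothing-minus-body angle differences
   during quiet standing, at IC, and at the stance instant when the body
   shank passes vertical. Phase portraits (omega vs theta) summarize cycle
   shape and range.

The generator models each limb segment's sagittal angle with smooth periodic
angular-velocity templates whose extrema *are* the gait events (stance span
= 60% of the cycle by construction), derives IMU signals through a rigid
pendulum forward model (gravity + lever-arm accelerations, sensor noise,
gyro bias, random mounting rotations), and couples clothing to the limb
through a linear spring-damper with gain, amplitude noise, and
placement-specific stiffness.

## Worked example

```
$ clothgait simulate --out demo/session --seed 11 --cycles 40 --segment-duration 30
wrote session with 6 sensors and 40 ground-truth cycles to demo/session

$ clothgait run --session demo/session --out demo/results
Clothing-mounted vs body-mounted sensor agreement
subject: S1    clothing: jogging trousers
stance fraction (body cycles): 0.595

placement     n_cycles  corr.coef    standing (deg)  walking IC (deg)  shank-vert (deg)
waist               40      0.859     +0.00 ±  0.74     +1.83 ±  0.66     -1.03 ±  0.69
thigh               40      0.979     +0.02 ±  0.48     +5.85 ±  1.28     +5.04 ±  1.41
lower_shank         40      0.992     +0.01 ±  0.30     +4.15 ±  0.50     +2.06 ±  0.44
results written to demo/results
```

Reading the table: all 40 walking cycles were detected and none flagged; the
detected stance phase occupies 59.5% of the cycle (the canonical ~60/40
stance/swing split). Mean per-cycle correlations between the clothing- and
body-mounted sensor-to-vertical angles are high at the thigh and lower shank
(≥ 0.97) and lower at the waist (0.86), where fabric coupling is loosest —
the characteristic ordering for loose trousers. Angle differences are
centred on 0° during standing (both sensors aligned to vertical by the
calibration) and grow to a few degrees at initial contact, when the fabric
is accelerated hardest. `demo/results/` also contains per-cycle correlation
tables, cycle event tables, mean-cycle bands, phase-portrait data and the
composed alignment rotations as CSV; add `--plots` to render figures.

`clothgait compare --session <dir>` prints the table without writing files;
`clothgait report --results <dir>` re-renders a saved report.

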