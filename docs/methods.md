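# Methods

This note documents the models, numerical choices and limitations behind
`shoegait` — what the pipeline assumes, what the synthetic-data generator
does and does not emulate, and where the design was genuinely open.

## Frames and conventions

Ground/global frame: x lateral, y along the walking direction, z vertical
up. Shoe/IMU-local frame: x′ across the foot, y′ along the foot, z′ normal
to the sole. Quaternions are Hamilton, scalar-first (w, x, y, z), rotating
local vectors into the world frame. Euler angles are intrinsic z–y–x:
R = R_z(ψ)·R_y(φ)·R_x(θ). Angles are degrees at module boundaries and
radians internally. The accelerometer reports specific force, so a level
stationary sensor reads (0, 0, +9.81) m/s².

## Initial attitude

Two initial-angle estimators are provided. The legacy arctan pair

    θ0 = −atan2(a_z0, a_x0),  φ0 = arctan(a_x0 / √(a_y0² + a_z0²))

is implemented verbatim (`initial_angles`); it presumes a mounting in which
gravity at rest lies along the sensor x′ axis and is **not** consistent
with the z–y–x chain above: there is no attitude R with ψ=0 whose Euler
angles these formulas recover from R^T·(0,0,g). The pipeline therefore
initializes with the accelerometer-leveling form (`initial_angles_from_gravity`)

    θ0 = atan2(a_y0, a_z0),  φ0 = −arctan(a_x0 / √(a_y0² + a_z0²)),

which is algebraically exact for the chain: with R = R_y(φ)R_x(θ),
R^T(0,0,g) = (−g sinφ, g cosφ sinθ, g cosφ cosθ), and the formulas invert
this. Both require the stationary norm to be within 0.5 m/s² of 9.81. The
heading ψ0 is unobservable from gravity and is fixed at 0; stride length is
invariant under this choice (it is a horizontal norm).

## Orientation tracking

Per-sample relative rotations q_k ⊗ q_{k−1}⁻¹ are **composed** onto the
initial attitude and each pose is decomposed to z–y–x Euler angles, with
unwrapping to avoid ±180° jumps. Summing per-step Euler *increments*
instead would integrate the world angular velocity, which coincides with
the Euler-angle rates only for single-axis motion and leaves a
rate-independent error of several degrees for composed multi-axis motion;
composition is identical in the single-axis case and exact in general. A
warning is raised when |φ| exceeds 85°, where the z–y–x decomposition is
ill-conditioned (walking never approaches this).

## Accelerometer calibration

Model: a_cal = gain ∘ (a_raw − bias), six parameters, no cross-axis terms —
the minimal model for which stationary norms identify the parameters from
N ≥ 6 non-collinear postures (20 by default). The objective
Σ(‖gain∘(a_k−bias)‖ − 9.81)² is minimized by Gauss–Newton with
Levenberg-style diagonal damping from gain=(1,1,1), bias=(0,0,0); steps are
accepted only if the objective does not increase, damping shrinks ×10 on
acceptance and grows ×10 on rejection; convergence when the accepted step
norm < 1e−10 (max 100 iterations, after which a convergence error carries
the last iterate). The fit is cross-checked against
`scipy.optimize.least_squares` in the tests.

## Force branch

* 4th-order Butterworth low-pass at 50 Hz, applied zero-phase (filtfilt):
  analysis is offline and phase lag would shift stance-event timing; this
  doubles the effective order, and tests compare against the squared
  analytic magnitude response.
* Offsets are removed per channel as the median over unloaded samples. The
  bootstrap unloaded mask takes samples whose summed vertical force lies
  within 10 N of the 20th-percentile baseline; at least 0.1 s of unloaded
  data is required.
* Ground-frame transform R_y(φ)R_x(θ) per sample, with angles linearly
  interpolated from the 70 Hz IMU clock onto the 400 Hz force clock
  (end-clamped). Kinematics never resamples; only the angles cross clocks.
* Stance detection: total vertical force crossing 15 N, with debouncing —
  candidate stances separated by swings < 0.1 s are merged, stances
  < 0.2 s discarded (the threshold is published; the hysteresis is ours,
  sized well below physiological stance/swing durations).
* Each stance is linearly resampled to 101 points. Ten-percent segment
  summaries average samples 1–10, 11–20, …, 91–100, excluding the heel
  contact instant itself (sample 0), matching the 1–10% … 91–100% segment
  labels used for such profiles.
* Percentage contributions use signed segment means (shear components can
  legitimately be negative); a segment whose |total mean| < 1 N is
  reported as missing rather than divided, since signed totals can vanish.

## Kinematics branch

Global acceleration a = R_z(ψ)R_y(φ)R_x(θ)·a_local − (0,0,9.81). A
1.0–40 Hz 4th-order zero-phase band-pass is provided (`bandpass_accel`,
upper cutoff clipped to 0.45·fs, i.e. 31.5 Hz at the 70 Hz IMU rate, which
is below the 35 Hz Nyquist limit), but it is **not** applied before
integration: at self-paced cadence (~0.9 strides/s) the per-stride
displacement is carried by velocity content at and below 1 Hz, and the
1 Hz high-pass removes most of the stride length itself (≈87% loss on
noiseless synthetic gait) while its ringing (~3.8 m/s² at flat-window
midpoints) also defeats the stillness detector. The drift the filter
would target is instead cancelled by the per-stride ZUPT model below,
which removes any constant acceleration bias in closed form.

Flat-foot samples satisfy |‖a_raw‖ − 9.81| ≤ 0.8 m/s² AND ‖a_global‖ <
1.0 m/s², sustained ≥ 0.05 s. These constants are implementation choices:
the norm band tolerates residual calibration error, the dynamic bound sits
an order of magnitude below swing accelerations, and the sustain rejects
single-sample coincidences. One stride spans midpoint-to-midpoint of
consecutive flat-foot runs; the swing within a stride runs from the end of
the opening run to the start of the closing run.

Integration is trapezoidal (second-order, standard for ZUPT pipelines).
Per stride and axis, velocity integrates from zero; the residual
end-of-stride velocity v_err — zero in truth at the next flat foot — is
removed by subtracting the ramp v_err·(t−t0)/(t1−t0) (applied to all three
axes; for a constant bias b this correction is exact: v = b·t minus the
ramp is identically zero). Position integrates from the corrected
velocity, and the vertical position is additionally pinned to zero
displacement at stride end by the same ramp construction. Consequently end
velocity and end vertical displacement are exactly zero by design, which
the tests assert at 1e−12.

Stride length is the Euclidean horizontal displacement between the swing
start and the stride end (the foot is stationary across each flat-foot
run, so this equals the swing-start-to-swing-start displacement). Toe
clearance is z(t) + 0.03 m (the IMU mount height, configurable); it is not
clamped at zero so integration faults remain visible. The MTC is the
lowest interior local minimum of the clearance within 25–75% of the swing
(our operationalization of "mid-swing"); if the window contains no
interior minimum, its global minimum is used.

## Statistics

CV uses the sample (n−1) standard deviation over the mean and refuses
near-zero means. Group tests are Student pooled-variance unpaired t-tests
(Welch available as a flag); Cohen's d uses the pooled SD, consistent with
the pooled t. Stride length and MTC are normalized by participant height,
total GRF by body mass — heights differ systematically between cohorts
and correlate with the gait parameters, masses with the forces. Agreement
reports Pearson r, RMSE, mean difference (bias) and bias ± 1.96·SD(diff)
limits, all with (n−1) SDs. Tests are performed on participant-level
values (per-participant means first, then the group test). No
multiple-testing correction is applied.

## Synthetic gait generator

The generator is the study-condition definition, not a tuning knob. Group
profiles (defaults):

| parameter | young | older |
|---|---|---|
| normalized stride mean (stride/height) | 0.670 | 0.655 |
| normalized stride CV | 0.0534 | 0.0858 |
| normalized MTC mean (MTC/height) | 0.0196 | 0.0120 |
| normalized MTC CV | 0.30 | 0.71 |
| cadence (strides/s) | 0.93 | 0.85 |
| stance fraction | 0.60 | 0.63 |
| height (m) | 1.67 ± 0.066 | 1.54 ± 0.054 |
| mass (kg) | 60.2 ± 16.6 | 54.6 ± 7.9 |
| contact style | heel-first | flat |

Cadence and stance fraction are typical self-paced walking values; the
rest are the cohort statistics the profiles are meant to reproduce.
Stride lengths are Normal(mean, CV·mean). MTC is **lognormal** with
matching mean and CV: at CV = 0.71 a normal truncated at the 0.001 m
physical floor would be reshaped to an effective CV ≈ 0.54, so the target
variability would be unreachable by construction; the lognormal matches
both moments exactly and is naturally positive. Per-participant height
and mass are Normal draws clipped to physiological bounds.

The toe path is standing → (swing, flat-foot)×n. Swing forward motion is
a minimum-jerk quintic reaching the stride length; the vertical travel is
a sin³-enveloped low-order trigonometric curve whose **clearance**
(travel + 0.03 m) passes through 3×MTC at 25% swing, exactly the MTC with
zero slope at 50% (a sin(4πs) term cancels the asymmetry slope), and
2×MTC at 75%. The curve's harmonic content stays below ~4 cycles per
swing, matching the band-limited character of real foot motion — spikier
constructions (e.g. quintic splines through the same knots) carry snap
that a 70 Hz stream cannot represent and produce centimetre-level
discretization artefacts in the double integral that real feet do not.
Recorded truth MTC is the analytic minimum of the realized curve (within
~3 mm of the drawn value for the largest older-adult draws). Foot pitch
is a smooth plantarflexion/dorsiflexion wave about the lateral axis
(±25° amplitude heel-first, ±10° flat).

The IMU stream is the exact analytic second derivative plus gravity,
rotated into the pitching sensor frame, corrupted by the inverse
calibration (divide by gain, add bias) and white noise; quaternions carry
small random attitude errors. Default imperfections: accel noise SD
0.05 m/s², gains (1.03, 0.98, 1.02), biases (0.15, −0.10, 0.05) m/s²,
quaternion angle noise 0.2°, force noise 1.0 N, per-channel force offsets
SD 0.5 N — magnitudes typical of consumer MEMS parts and instrumented
insoles. Forces are emitted on an asynchronous 400 Hz clock: the total
vertical force is a double-bump curve peaking near 1.1 body weights, the
fore–aft force a braking/propulsion wave, distributed across the four
sensors by smooth weight curves (heel early / MT5 mid / toe late for
heel-first; early load shifted toward toe and metatarsals for the flat
style). These waveforms are plausibility templates: they exercise the
force pipeline and carry the qualitative contact-style contrast, but no
quantitative agreement of contribution percentages with measured curves
is claimed.

What the simulator does **not** emulate: turning or non-straight paths,
slopes and stairs, soft-tissue and shoe compliance, sensor saturation,
heel-strike transients in the IMU, stance-phase toe motion (the toe is
perfectly still whenever it is down, so the zero-velocity assumption holds
exactly in the noiseless limit), and any coupling between force and
kinematic noise. Passing tests therefore demonstrate the correctness of
the algorithm chain under the stated measurement model, not field accuracy
on real shoes.

## Problem sizes

The verification runs use desk-scale sizes chosen to give stable Monte
Carlo estimates: recovery RMSE over 105 strides (7 sessions × 15 strides)
and cohort statistics over 20 repetitions of 15 participants × 10 strides
(300 sessions); the whole acceptance computation completes in seconds.

## Known limitations

* The heading angle ψ is initialized to zero and evolves only through the
  quaternion stream; magnetometer correction is out of scope.
* Stride counts rely on flat-foot detection; pathological gait without
  clear flat phases (e.g. toe-walking) would defeat the segmentation, and
  the thresholds were not designed for it.
* The MTC search assumes the canonical two-peak clearance shape; gait with
  a monotone mid-swing clearance falls back to the window minimum.
* Contribution percentages for shear directions are signed and can exceed
  100% or be negative when sensors oppose each other; segments with
  near-zero totals are reported as missing.
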