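# Methods

This note documents the models, conventions, numerical choices and known
limitations of strikelab.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and angle conventions

Tracker exports use image-style pixel coordinates (y typically down).
All joint angles are *interior* angles obtained from the dot-product /
arc-cosine of the two joint vectors, so every kinematic quantity is
invariant under translation, rotation, uniform scaling and y-axis flips
of the input coordinates; no axis convention needs to be declared by the
user.  Units on disk are pixels, millinewtons and seconds; conversion to
SI happens exactly once (mm/pixel scale in the kinematics module, mN→N in
the power module).

Standardized angles are stored **opening-positive**, i.e.
`θ(t) − θ(0)`, so that joint opening, angular velocity and power all
carry the same sign.  The alternative initial-minus-raw convention
(`θ(0) − θ(t)`) is available via `standardize_angles(..., literal=True)`
and recorded in the series metadata; it differs only by sign.

## Strike segmentation

The strike onset is "the moment the CT joint starts to increase after
having been completely closed"; the end is "the spur stops penetrating".
These verbal rules are operationalized as:

1. **Closed level and plateau.**  A running median (kernel 5,
   edge-replicated) suppresses tracker-noise spikes.  The closed level is
   the minimum of the smoothed CT series; the plateau is the longest run
   of ≥ `min_plateau` frames (default 5) whose smoothed angle stays
   within `closed_tolerance` (default 1°) of that level.
2. **Onset.**  An anchor is the first frame whose raw angle exceeds the
   tolerance band for `rise_persistence` (default 3) consecutive frames.
   The start frame is one past the last frame before the anchor whose raw
   angle is within 3 robust SD of the closed level.  The noise SD is
   estimated from *second differences* over the plateau run
   (σ̂ = 1.4826·MAD(Δ²θ)/√6), which is exactly zero for any noise-free
   piecewise-linear angle program — so on noise-free data the detected
   start is exactly the first rising frame, at any opening rate, while
   under tracker noise the 3σ band rejects spurious early crossings.
3. **End.**  First frame after the tip-speed peak where the tip speed
   falls below `end_speed_frac` (default 5 %) of the peak (an absolute
   threshold in m/s can be supplied instead).  If the speed never falls
   below threshold the last frame is used and a warning logged.

Degenerate frames (coincident landmarks) abort with a frame- and
joint-indexed error rather than being interpolated: silent repair would
corrupt the velocity estimates downstream.

## Differentiation

The default angular-velocity estimator is a Savitzky–Golay derivative
(polynomial order 2, window 5), appropriate at ≥ 10,000 fps; plain
central differences are available.  Both are exact for constant-rate
openings; on noisy constant-slope ramps the S–G estimate has lower mean
squared error than the central difference (verified by simulation in the
test suite).  Tip speed uses central differences of the tarsus-base
positions.  The source recordings do not state a smoothing scheme, so
the default here is a declared choice.

## Power output

Two muscle-mass-specific power constructions are implemented behind one
interface, the two standard ones for latch-mediated spring actuation
(LaMSA) analyses:

* **instantaneous**: `mpo = F_peak · v_tip,peak / m_muscle`;
* **energetic**: `mpo = ½ I ω_peak² / (T_sweep · m_muscle)` with
  I assembled from uniform rods about their proximal ends (m L²/3) and
  point masses (m r²) about the CT joint.

They measure different quantities (peak instantaneous power vs mean
power over the sweep) and are expected to disagree by a factor of ~2;
only positivity and their scaling laws are asserted.  The verdict is
`amplified` iff **both** exceed the upper direct-muscle limit
(100–500 W kg⁻¹ range; upper bound 500 W kg⁻¹ used), `within_muscle_limits`
iff both are at or below it, `indeterminate` otherwise.  The
amplification ratio is min(mpo)/500.

Muscle mass has **no silent default**: it must be measured (mg) or
derived from body mass via an explicitly supplied fraction.  The default
lever arm is the measured CT-joint→tarsus-base distance at strike start.
`torque_power_consistency` cross-checks F·v against (F·r)·ω and is zero
exactly when the tip moves in pure rotation (v = ωr).

## Synthetic world

The generators state one fixed world at the magnitudes of the real
recordings; their defaults are not tuned to any test outcome.

* **Strike tracks**: 20,000 fps, mm-scale leg segments (coxa 4 mm,
  trochanter–femur 8 mm, tibia 4 mm, scale 0.05 mm/px), CT joint closed
  at 15° opening at 500 rad/s for 1.6 ms (≈ 46° excursion), FT joint
  static at 105° during the sweep.  The opening is a constant-rate ramp,
  so per-frame ground truth is exact and frame-quantized: the
  ground-truth end frame is the first frame at rest, and the sweep
  duration is an exact multiple of 1/fps.  Landmark noise is i.i.d.
  Gaussian in pixels; its magnitude is a free parameter (the source
  recordings report none).
* **Force traces**: baseline + linear drift + a pulse rising linearly to
  its peak (snapped to the sample grid, so the analytic peak is attained
  exactly) with exponential decay; defaults echo a ~17.6 mN strike.
* **Model trials**: a tensile ramp at the nominal 10 mm/s pull rate to a
  release force with log-normal trial scatter, then a tracked point
  moving along a straight line whose per-frame displacement integrates a
  gamma-shaped speed profile — the frame-to-frame speed therefore equals
  the programmed profile exactly, and its peak is the programmed peak.
  The force→speed map saturates at the spring saturation force: release
  forces above it store no additional energy and leave the peak speed
  unchanged.  Cell means default to the measured trial means
  (forces 22.38/0.55 N stiff, 18.63 N flexible high-friction; speeds
  0.205/0.056 m/s flexible, 0.075 m/s stiff), with the log-force
  structure made exactly additive (no type × friction interaction) and
  the stiff trochanter given a null friction effect on speed — i.e. the
  generator encodes the study's *inferred* effect structure, not its
  sample noise.  Per-sample random intercepts (SD 0.25 on log-force,
  0.015 m/s on speed) are drawn once per sample in the design builder,
  mirroring the random-intercept term of the analysis model; residual
  scatter is 0.2 (log-force) and 0.02 m/s.

What a green test does **not** establish: the generators contain no
tracking-algorithm failure modes, no correlated (drifting) landmark
noise, no transducer ringing, and the model-trial motion is straight-line
rather than rotational — so the tests validate the estimators'
correctness and statistical calibration, not robustness to every
real-world artefact.

## Mixed-effects analysis

`log(force) ~ type × friction + (1|sample)` and
`velocity ~ type × friction + (1|sample)`, fitted by REML
(statsmodels `MixedLM`).  Choices:

* **Factor coding**: explicit sum-to-zero (±1) columns; Type III tests
  are then single-coefficient Wald tests, well defined and invariant to
  factor-level ordering.
* **Degrees of freedom**: Wald chi-square / normal approximations
  throughout — the backend offers no Satterthwaite correction; with the
  balanced 128-observation design the approximation is mild (false-positive
  calibration is verified by simulation in the acceptance suite).
* **Numerics**: the response is internally standardized before
  optimization (velocities of ~0.05 m/s otherwise ill-condition the
  profiled likelihood) and estimates are mapped back exactly; the
  optimizer cascade is BFGS → CG → Powell.  Tiny negative variances from
  boundary fits (zero random-intercept variance) are clipped at zero.
* **Transform**: force is analysed on the natural-log scale
  (heteroscedastic on the original scale); the transform is recorded on
  the result and exponentiation is lossless.
* **Contrasts**: within-type high-vs-low-friction Wald z contrasts,
  *unadjusted* for multiplicity (recorded as such in the report); EMMs
  are reported on the model scale.
* A note on units: the source material labels the model velocities
  "ms⁻²" while calling them velocities; strikelab treats them as linear
  speeds in m/s throughout.

## Spiral geometry

Arc length uses the closed form
`L = (1/k)·[r√(r²+k²)/2 + (k²/2)·asinh(r/k)]` between the end radii,
with the exact circle-arc limit `r₀·Δθ` at k = 0.  Arms 3–4 of the
double spiral are the point reflections (rotation by π) of arms 1–2 — a
declared, pluggable derivation rule carried in the geometry metadata.
Arm intersection (checked with shapely) produces a warning, not an
error: an overlapping design is printable but will not deform as
independent coils.  Model units are dimensionless; exports carry a unit
tag.  No stiffness or material model is attempted — spring tuning (coil
count via θ range, scale, extrusion height) is a manufacturing concern
outside this layer.

## Reproducibility

Seeds are explicit scenario fields, never global state; identical
scenario + seed gives bit-identical output.  Result writers emit
full-precision (`%.17g`) floats and a manifest without timestamps, so a
rerun with the same inputs is byte-identical; readers parse with
round-trip float precision.

## Numerical tolerances in the validation suite

Ground-truth recovery of noise-free strikes is asserted at 1e-6 relative
error; the recovery tests therefore sample at 1 Mfps, where the
finite-difference discretization error of a rotating point,
~(ωΔt)²/6 ≲ 2e-7 at ω = 1000 rad/s, sits below the tolerance.  This is a
numerical-convergence check; segmentation robustness is tested
separately at realistic video rates (20 kfps) under calibrated landmark
noise.

## Known limitations

* Planar (2-D) kinematics only; out-of-plane motion biases angles and
  speeds toward zero.
* The tibia tip is identified with the tarsus-base tracker; if the spur
  tip lies distal to it, tip speeds underestimate the true spur speed.
* The exact formulations behind the two published mpo estimates are not
  part of the available text; the two constructions implemented here are
  declared stand-ins with the same structure (two estimates of different
  magnitude) and are isolated behind one interface so alternatives can
  be swapped in.
* The prey-size/day/animal group comparison is descriptive plumbing (the
  original test is unnamed); it uses Kruskal–Wallis on the available
  summaries.
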