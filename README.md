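# strikelab

Biomechanics toolkit for analysing an ultrafast *impaling* predatory
strike — the kind of latch-mediated spring-actuated (LaMSA) motion a moss
mantis uses to spear minute prey with its modified raptorial forelegs —
together with the physical catapult model used to demonstrate the
mechanism.

It is written for comparative biomechanists and functional morphologists
who have (a) landmark tracks exported from high-speed video
(12,000–20,000 fps), (b) force–time traces from a force transducer, and
(c) tensile-test trials of a 3D-printed proof-of-concept model, and who
want reproducible kinematics, power-output verdicts and mixed-effects
statistics — plus synthetic generators with exact ground truth so every
stage can be validated without the original recordings.

## What it computes

**Strike kinematics.** Five landmarks are tracked per frame (body at the
forewing base, coxal base, coxa–trochanter joint, femur–tibia joint,
tarsus base).  From the joint vectors, the CT and FT interior angles
θ_CT, θ_FT are computed per frame, standardized to frame 0, and
differentiated (Savitzky–Golay, order 2, window 5, by default) to ω(t) in
rad/s; the tarsus-base landmark gives the tip speed v(t).  The strike is
segmented into the closed-CT plateau, the onset (the moment θ_CT starts
to rise after the joint was completely closed) and the end (tip speed
falling below 5 % of its peak — the spur has stopped penetrating).

**Force analysis.** Transducer traces are baseline-corrected
(pre-window median), and each strike yields its peak force F_peak, the
median force over the strike window, and the body-mass-specific force
F_peak / m_body.  Groups (animal / day / prey-size class) are compared
with a rank-based Kruskal–Wallis test at α = 0.05.

**Muscle-mass-specific power output (mpo).** Two standard constructions,
compared against the direct-muscle performance ceiling of 100–500 W kg⁻¹:

- instantaneous:  `mpo₁ = F_peak · v_tip,peak / m_muscle`
- energetic:      `mpo₂ = ½ I ω_peak² / (T_sweep · m_muscle)`,
  with I the leg's moment of inertia about the CT joint (rod + point-mass
  model).

The verdict is **amplified** only when *both* estimates exceed the upper
limit — evidence that elastic energy storage, not direct muscle
contraction, drives the motion.

**Double-spiral spring geometry.** The flexible artificial trochanter of
the physical model carries a planar spring of Archimedean spiral arms
r(θ) = r₀ + kθ (reference design: θ ∈ [0, 2π], k = 2, r₀ = 11 and 14.5;
arms 3–4 are point reflections of arms 1–2).  The module generates the
polylines, computes closed-form arc lengths, and exports SVG/CSV.

**Physical-model experiment.** Per trial, the maximum tensile force
before release and the post-release tracked-point speed are extracted,
then analysed with linear mixed-effects models,

```
log(force) ~ type × friction + (1 | sample)
velocity   ~ type × friction + (1 | sample)
```

with sum-to-zero coding, Type III Wald tests, estimated marginal means
per type × friction cell and within-type pairwise friction contrasts.

## Worked example

Simulate one strike at in-vivo magnitudes (20 kfps, ~1.6 ms sweep,
~17.6 mN peak force, 1.5 mg extensor muscle) and analyse it:

```bash
strikelab simulate --n-strikes 1 --seed 1 --out demo
strikelab power --config demo/config.yaml \
    --track demo/strike_000_track.csv --trace demo/strike_000_force.csv
```

prints

```
mpo_inst      = 73704.1 W/kg
mpo_energetic = 10087.9 W/kg
verdict       = amplified (ratio 20.2x the 500 W/kg muscle limit)
```

Both power estimates are one to two orders of magnitude above what direct
muscle contraction can deliver (≤ 500 W kg⁻¹): the strike must be driven
by a power-amplification (LaMSA) mechanism.  The two estimates differ by
design — they measure different quantities (peak instantaneous power vs
mean power over the sweep) and no ordering between them is assumed.

The same thing from Python:

```python
from strikelab.pipeline import simulate_strike_bundle, run_strike_pipeline

pairs, config = simulate_strike_bundle(n_strikes=5, seed=1)
results = run_strike_pipeline(pairs, config)
print(results["study"][["mean_mpo_inst_W_kg", "verdict"]])
```

Other entry points: `strikelab kinematics` (per-frame angle/velocity
table), `strikelab forces` (per-strike force summaries),
`strikelab spiral` (double-spiral SVG/CSV export),
`strikelab model-experiment` (simulated physical-model study with the
full LME report), `strikelab run-all` (pipeline + manifest).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch — the synthetic
strike pipeline with its LaMSA verdict, the double-spiral arc-length
check against the closed form, and the physical-model mixed-effects
analysis — printing a run summary and writing the results JSON to
`--out`.  All randomness derives from `--seed`.
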