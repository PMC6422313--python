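# Methods

## Model

`lateralstep` models the *between-step* regulation of lateral stepping as a
discrete map over steps, not the within-step biomechanics.  The state of a
walker at step *n* is the pair of lateral foot placements
(z_L(n), z_R(n)); equivalently the pair (z_B, w) of body position
(midpoint of the feet) and step width, an exact invertible linear change
of coordinates.  Heading Δz_B(n) = z_B(n) − z_B(n−1) is the first
difference of position and is undefined at step 0; all analyses consume
the shortened length-(N−1) series rather than a padded one.

A uni-objective regulator picks one variable
q ∈ {z_B, Δz_B, w} and iterates

    q(n+1) = q(n) + g·(1 + σ_m ν_m)·u(q(n)) + σ_a ν_a
    u(q)   = −G·(q − q*),   G = 1/(1 + σ_m² + γ/α)

where ν_m, ν_a are iid standard normal (multiplicative and additive motor
noise), g is a tuning gain, and G is the stochastically optimal feedback
gain for the one-step expected cost α·(q(n+1) − q*)² + γ·u².  G lies in
(0, 1], decreases monotonically in both σ_m² and γ/α, and equals 1 (full
single-step correction, unbiased proportional control) only when
σ_m = γ = 0.  In the absence of noise the goal-level error contracts
geometrically at rate (1 − g·G) per step.

### Foot-placement mechanics

The controller's 1D map prescribes only its own variable's next value.
One foot is newly placed per step, alternating sides, the other carried
over.  The swing foot is placed at the unique position realizing the
controller's target given the stance foot:

- width: z_new = stance ∓ w_target (swing left/right),
- position: z_new = 2·z_B_target − stance,
- heading: z_new = 2·(z_B(n) + Δz_B_target) − stance.

All non-controlled variables then follow passively from geometry — this is
what produces the drift signatures (e.g. under width-only control, position
performs an alternating-sum random walk with DFA α ≈ 1.5).  The heading
controller's state at step 0 is initialized to 0 (its goal value), since
Δz_B does not exist before step 1.  Step 0 of every simulated trial records
the initial two-foot configuration; its `placed_side` is set to the
opposite of the first swing side so that alternation holds over the whole
trial.

### Multi-objective mixtures

Two controllers with *distinct* variables run in parallel, each with its
own independent noise stream.  Each proposes a swing-foot placement; the
foot is placed at (1−ρ)·candidate₁ + ρ·candidate₂, and both controllers
then observe the realized geometry on the next step.  The mixing acts on
*placements*, not control inputs; the two 1D maps are uncoupled except
through the shared foot.  Noise streams are keyed by controlled-variable
identity (a fixed spawn key per variable on the trial's seed sequence), so
an objective's stream is the same whether it runs alone or in a mixture —
the ρ = 1 mixture with the other objective's noise zeroed is bit-identical
to the corresponding uni-objective simulation, which the tests exploit.

### Constraints

Constrained simulations project each candidate placement onto the feasible
interval: the intersection of the lateral boundary [−z_max, +z_max] with
the placements whose implied step width lies in [w_min, w_max].  Projection
(rather than resampling or rejection) keeps the simulation deterministic
for a given seed; per-step flags record which limit bound each clamp.  An
empty feasible interval (possible only for inconsistent configurations)
raises an error.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| z_B*, Δz_B* | 0 | m | stay centered on the path, walk straight |
| w* | 0.127 | m | typical mean human step width |
| σ_a | 0.025 | m | additive motor-noise SD |
| σ_m | 0.0025 | — | multiplicative noise SD, 0.1 × σ_a numeric |
| γ/α | 0.1 | — | effort-to-error cost ratio |
| g | 1 | — | tuning gain (the derived optimal controller) |
| ρ | 0.93 | — | weight on step-width control in the headline mixture |
| z_max | 0.885 | m | treadmill half-width |
| w_min, w_max | −0.0015, 0.2554 | m | mean ± 5 SD human step-width range |
| n_steps | 290 | — | steps per trial |
| n_trials | 30 | — | simulated replicates per condition (65 for the reference fixture) |

At these defaults G = 1/(1 + 0.0025² + 0.1) ≈ 0.909: each controller
corrects ~91% of its current error per step.  `calibrate_additive_noise`
inverts the stationary-SD relation σ_stat = σ_a/√(1 − (1−gG)²) of the
AR(1) approximation (multiplicative noise neglected; optional
simulation-based refinement available) for matching a target output SD.

σ_m is dimensionless in the map but its default is tied numerically to
σ_a ("0.1 × σ_a expressed in meters"); at baseline its effect on G is
negligible (σ_m² ≈ 6×10⁻⁶) and it mainly adds state-dependent noise.

## Dependent measures

- **σ**: sample standard deviation (n−1 denominator) per series.
- **DFA α**: the series is mean-centered and cumulatively summed; for each
  of 50 segment lengths *j* evenly (linearly) distributed on [4, ⌊N/4⌋]
  (rounded to integers, duplicates dropped; log spacing available but
  non-default), the profile is split into ⌊N/j⌋ non-overlapping segments
  anchored at the series start, the tail remainder discarded; a
  least-squares line is removed per segment and F(j) is the RMS residual
  over covered points.  α is the least-squares slope of log F vs log j
  (natural log; the slope is base-invariant).  Constant series and series
  shorter than 16 points are rejected.
- **Direct control regression**: OLS of Δq(n+1) = q(n+1) − q(n) on
  q′(n) = q(n) − q̄ over n = 0…N−2, returning slope, intercept, r².  For an
  AR(1) series with coefficient φ the slope estimates φ − 1, so a
  regulator correcting a fraction G of its error per step shows slope ≈ −G
  in its controlled variable.

`summarize_trial` applies all three to z_B, Δz_B and w plus σ and α of
z_L and z_R.  Degenerate series (e.g. constant w from a noise-free
simulation — constant up to ~1-ulp reconstruction round-off) report NaN
for the affected measures rather than failing the whole trial.

## Model comparison

Acceptance of a model on a measure follows the band rule: the mean across
its simulated trials must lie within the reference mean ± 1 SD.  Sweep
aggregation reports mean ± 95% CI (1.96·SEM across trials; the CI is
descriptive and plays no role in the verdict).  The default sensitivity
grid crosses ρ ∈ {0.89, 0.91, 0.93, 0.95, 0.97} with five parameter
variants (baseline, γ/α ∈ {0, 0.2}, σ_a scaled by 0.9 and 1.1).  For
constrained conditions, violation percentages are additionally computed on
unconstrained twins (same seeds, no clamping) to show whether the
condition is feasible without enforcement.

## Reference fixture

`generate_reference_fixture` produces a synthetic stand-in for a human
reference data set: 65 trials × 290 steps (matching a 13-participant ×
5-trial design) from the constrained ρ = 0.93 position–width model at
baseline parameters — the configuration that reproduces the human
pattern.  Its trials show mean step width ≈ 0.127 m with SD ≈ 0.025 m,
strongly persistent position (α(z_B) ≈ 1.2), anti-persistent heading
(α(Δz_B) ≈ 0.49), weakly persistent width (α(w) ≈ 0.55), width
error-correction slope ≈ −0.85 with r² ≈ 0.4, and position slope ≈ −0.07
with r² ≈ 0.03 (all recomputed by the tests).

What the fixture does *not* emulate: inter-participant heterogeneity
(every trial comes from one parameter set, so its between-trial SDs are
narrower than human between-participant SDs), measurement noise, drift or
fatigue within a trial, and any within-step dynamics.  Tests passing
against the fixture therefore demonstrate internal consistency of the
modelling and analysis chain and reproduction of the qualitative human
pattern — not agreement with any particular human data set.  The
comparison machinery is source-agnostic: bands built from analyzed human
trials in the same `stats.csv` schema can be substituted directly.

## Numerical choices

- Doubles throughout; meters everywhere internally and in files.
- Trial files are delimited text (`step,side,z_L,z_R`) written with
  `repr`-precision floats and read back with round-trip float parsing, so
  file I/O is lossless.
- Per-trial seeds are drawn from a `SeedSequence` on the base seed
  (`generate_state`, 32-bit words); per-objective streams use fixed
  spawn keys per variable.  Identical configuration + seed ⇒ bit-identical
  trials; the CLI writes a manifest with the resolved parameters and seed
  from which every output is reproducible.
- The feet ↔ (z_B, w) round trip is exact to ≤ 1 ulp of the
  larger-magnitude coordinate (exact for same-magnitude feet and for the
  decimal examples in the tests); the residual is ordinary rounding of the
  midpoint/half-width recombination.
- Clamp-flag tie-break: if the boundary and width limits coincide at the
  binding endpoint, both flags are set.
- Step-0 conventions as above (initial configuration recorded; heading
  state seeded at 0).

## Known limitations

- The swing-foot mechanics are the minimal mechanism consistent with
  alternating single-foot placement; richer mechanics (e.g. within-step
  CoM dynamics, velocity-dependent placement) are out of scope.
- Regulators are linear with Gaussian noise; the direct-control analysis
  can detect but the models cannot produce error-magnitude-dependent
  (nonlinear) correction.
- The unconstrained heading regulator lets position wander without bound;
  long unconstrained simulations of it can drift far off any physical
  path (by design — that is the failure mode the comparison machinery is
  meant to expose).
- Sweep runtimes scale linearly in conditions × trials × steps; the
  default grid (25 × 30 × 290, constrained + unconstrained twins) runs in
  seconds to tens of seconds on one CPU.
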