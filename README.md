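# lateralstep

Stochastic optimal "control templates" for the step-to-step regulation of
lateral stepping during walking.

When people walk, every step is a choice: infinitely many lateral foot
placements keep the walker on the path, so which deviations does the nervous
system correct, and which does it let drift?  `lateralstep` implements a
family of discrete-map regulator models that answer this question, plus the
fluctuation analyses used to decide which model reproduces human stepping
dynamics.

## The model

Each step is summarized by the left/right lateral foot placements
(z<sub>L</sub>, z<sub>R</sub>), from which three candidate control variables
follow exactly:

- lateral body position z<sub>B</sub> = (z<sub>L</sub> + z<sub>R</sub>)/2,
- heading Δz<sub>B</sub>(n) = z<sub>B</sub>(n) − z<sub>B</sub>(n−1),
- step width w = z<sub>R</sub> − z<sub>L</sub>.

A regulator treats one variable q ∈ {z<sub>B</sub>, Δz<sub>B</sub>, w} as the
state of a 1D map over steps n:

    q(n+1) = q(n) + g·(1 + σ_m ν_m)·u(q(n)) + σ_a ν_a

with additive and multiplicative motor noise (ν iid standard normal).  The
control input minimizing the expected one-step cost α·error² + γ·u² is
proportional feedback

    u(q) = −G·(q − q*),    G = 1 / (1 + σ_m² + γ/α)   (0 < G ≤ 1),

reducing to full one-step error correction u = −(q − q*) when σ_m = γ = 0.
The controller only prescribes its own variable's next value; the swing foot
(one per step, alternating sides) is placed at the unique position realizing
it, and every other variable drifts passively under the geometry.  A
multi-objective regulator runs two such controllers in parallel and places
the foot at the weighted average of their two predicted placements (weight ρ
on the second objective).  Constrained simulations project each placement
onto the feasible interval set by the path boundary (|z| ≤ 0.885 m) and
step-width limits (−0.0015 m ≤ w ≤ 0.2554 m).

Model selection uses three dependent measures per variable: the standard
deviation σ, the detrended fluctuation analysis (DFA) scaling exponent α
(≈ ½ uncorrelated, > ½ persistent, < ½ anti-persistent, ≈ 1½ Brownian), and
the direct error-correction regression of Δq(n+1) on q′(n) = q(n) − q̄
(slope ≈ −1: strong single-step correction; ≈ 0: none).  A candidate model
is consistent with a reference data set on a measure when its mean across
simulated trials falls within the reference mean ± 1 SD band.

The headline result this package reproduces: uni-objective regulators fail
to match human stepping dynamics, but a multi-objective mixture weighted
~93% step-width / ~7% position control matches the human pattern — strongly
persistent position (α ≫ ½), anti-persistent heading (α < ½), weakly
persistent step width (½ < α ≪ 1½), step-width correction slope near −1 with
high r², position slope near 0 with low r².

## Worked example

```python
from lateralstep import ConstraintSpec, SimulationConfig, simulate_trials
from lateralstep.experiments import baseline_position_width_model, stats_frame

model = baseline_position_width_model()          # rho = 0.93 position-width mixture
config = SimulationConfig(n_steps=290, n_trials=30, seed=1)
trials = simulate_trials(model, config, ConstraintSpec())
stats = stats_frame(trials)
for m in ("sd_zB", "sd_w", "alpha_zB", "alpha_dzB", "alpha_w", "slope_w", "slope_zB"):
    print(f"{m:>9s}  {stats[m].mean():+.3f}")
```

prints

```
    sd_zB  +0.043
     sd_w  +0.025
 alpha_zB  +1.184
alpha_dzB  +0.499
  alpha_w  +0.547
  slope_w  -0.849
 slope_zB  -0.070
```

i.e. body position wanders with strong persistence (α ≈ 1.2) and is barely
corrected step to step (slope ≈ −0.07), while step width is held near
0.127 m with SD ≈ 0.025 m, weak persistence (α ≈ 0.55) and strong one-step
error correction (slope ≈ −0.85) — the human-like signature.

## Command line

```sh
lateralstep simulate --mode multi --rho 0.93 --seed 7 --constrained --out runs/base
lateralstep analyze  --in runs/base --out runs/base/stats.csv
lateralstep fixture  --seed 11 --out reference/          # synthetic human-like reference
lateralstep sweep    --seed 17 --out sweep.csv           # 25-condition sensitivity grid
lateralstep compare  --stats sweep.csv --bands reference/bands.csv --out verdicts.csv
```

Every simulation directory contains a `manifest.json` with the resolved
parameters and seed; the same seed always reproduces byte-identical output.

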