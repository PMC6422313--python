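"""Stochastic optimal step-to-step regulators of lateral stepping.

Each regulator treats one stepping variable ``q`` — lateral body position
``z_B``, heading ``dz_B``, or step width ``w`` — as the state of a 1D
discrete map over steps::

    q_{n+1} = q_n + g * (1 + sigma_m * nu_m) * u(q_n) + sigma_a * nu_a

with multiplicative (``sigma_m * nu_m``) and additive (``sigma_a * nu_a``)
motor noise (``nu`` iid standard normal) and a tuning gain ``g``
(default 1).  The control input minimizing the expected one-step cost
``alpha * error^2 + gamma * u^2`` is proportional feedback::

    u(q_n) = -G * (q_n - q*),    G = 1 / (1 + sigma_m^2 + gamma/alpha)

so ``0 < G <= 1``; with no multiplicative noise and no effort cost
(``sigma_m = gamma = 0``) the controller reduces to unbiased one-step
correction ``u = -(q_n - q*)``.

The regulator only prescribes the next value of its own variable.  The
swing foot (one per step, alternating sides) is then placed at the unique
lateral position that realizes that value given the stance foot; every
other stepping variable follows passively from geometry ("drifts" under
motor noise).  A multi-objective regulator runs two such controllers in
parallel — each with its own noise stream — and places the foot at the
weighted average of their two predicted placements (weight ``rho`` on the
second objective), after which both controllers observe the realized
geometry.

Constrained simulations project each candidate placement onto the
feasible interval given by the lateral path boundary (``|z| <= z_max``)
and the step-width limits (``w_min <= w <= w_max``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

from .geometry import FootPlacementTrial

__all__ = [
    "VARIABLES",
    "RegulatorSpec",
    "MultiObjectiveSpec",
    "ConstraintSpec",
    "SimulationConfig",
    "optimal_gain",
    "control_input",
    "state_update",
    "swing_foot_for_target",
    "clamp_to_constraints",
    "simulate_uni_objective",
    "simulate_multi_objective",
    "simulate_trials",
    "trial_seeds",
    "violation_rates",
    "calibrate_additive_noise",
]

#: Controlled-variable tags (ASCII forms of z_B, Δz_B, w).
VARIABLES = ("z_B", "dz_B", "w")

_ALIASES = {
    "z_B": "z_B", "zB": "z_B", "position": "z_B",
    "dz_B": "dz_B", "dzB": "dz_B", "heading": "dz_B",
    "w": "w", "width": "w", "step_width": "w",
}

# Fixed per-variable keys for deriving independent noise sub-streams, so
# that a given objective's stream does not depend on whether it runs alone
# or inside a multi-objective mixture.
_VAR_STREAM_KEY = {"z_B": 0, "dz_B": 1, "w": 2}

#: Baseline goal values, meters (w* from the typical human mean step width).
DEFAULT_GOALS = {"z_B": 0.0, "dz_B": 0.0, "w": 0.127}

#: Baseline additive noise SD, meters.
BASELINE_SIGMA_A = 0.025
#: Baseline multiplicative noise SD (dimensionless, = 0.1 x sigma_a numeric).
BASELINE_SIGMA_M = 0.1 * BASELINE_SIGMA_A
#: Baseline effort-to-error cost-weight ratio gamma/alpha.
BASELINE_GAMMA_OVER_ALPHA = 0.1


def canonical_variable(name: str) -> str:
    """Map a variable alias (``zB``, ``width``, ...) to its canonical tag."""
    try:
        return _ALIASES[name]
    except KeyError:
        raise ValueError(
            f"unknown stepping variable {name!r}; expected one of {sorted(_ALIASES)}"
        ) from None


def optimal_gain(sigma_m: float, gamma_over_alpha: float) -> float:
    """Effective feedback gain ``G = 1 / (1 + sigma_m^2 + gamma/alpha)``.

    ``G`` is the fraction of the current goal-level error corrected per
    step; it decreases with multiplicative noise and with the relative
    cost of control effort, and equals 1 only in the noise-free,
    cost-free limit.
    """
    if sigma_m < 0:
        raise ValueError(f"sigma_m must be >= 0, got {sigma_m}")
    if gamma_over_alpha < 0:
        raise ValueError(f"gamma_over_alpha must be >= 0, got {gamma_over_alpha}")
    return 1.0 / (1.0 + sigma_m**2 + gamma_over_alpha)


@dataclass(frozen=True)
class RegulatorSpec:
    """One controlled variable's goal, noise levels and cost weighting.

    Attributes
    ----------
    variable
        ``"z_B"`` (lateral position), ``"dz_B"`` (heading) or ``"w"``
        (step width); aliases ``zB``/``dzB``/``position``/``heading``/
        ``width`` accepted.
    q_star
        Goal value in meters.  Defaults: 0 for position and heading,
        0.127 m for step width.
    sigma_a
        Additive motor-noise SD, meters (baseline 0.025).
    sigma_m
        Multiplicative motor-noise SD, dimensionless (baseline 0.0025).
    gamma_over_alpha
        Effort-to-error cost-weight ratio, >= 0 (baseline 0.1).
    g
        Tuning gain scaling the optimal control input (default 1: the
        derived optimal controller itself).
    """

    variable: str
    q_star: float | None = None
    sigma_a: float = BASELINE_SIGMA_A
    sigma_m: float = BASELINE_SIGMA_M
    gamma_over_alpha: float = BASELINE_GAMMA_OVER_ALPHA
    g: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable", canonical_variable(self.variable))
        if self.q_star is None:
            object.__setattr__(self, "q_star", DEFAULT_GOALS[self.variable])
        if self.sigma_a < 0:
            raise ValueError(f"sigma_a must be >= 0, got {self.sigma_a}")
        if self.sigma_m < 0:
            raise ValueError(f"sigma_m must be >= 0, got {self.sigma_m}")
        if self.gamma_over_alpha < 0:
            raise ValueError(f"gamma_over_alpha must be >= 0, got {self.gamma_over_alpha}")
        if self.g <= 0:
            raise ValueError(f"g must be > 0, got {self.g}")

    @property
    def gain(self) -> float:
        """The optimal feedback gain G for this spec."""
        return optimal_gain(self.sigma_m, self.gamma_over_alpha)

    def with_noise_zeroed(self) -> "RegulatorSpec":
        return replace(self, sigma_a=0.0, sigma_m=0.0)


@dataclass(frozen=True)
class MultiObjectiveSpec:
    """Two uni-objective regulators mixed at the foot-placement level.

    ``rho`` is the weight on ``spec2``'s predicted placement (weight
    ``1 - rho`` on ``spec1``'s).  Convention for the headline
    position–width model: spec1 = position, spec2 = step width, so
    "93% step width control" means ``rho = 0.93``.
    """

    spec1: RegulatorSpec
    spec2: RegulatorSpec
    rho: float

    def __post_init__(self) -> None:
        if self.spec1.variable == self.spec2.variable:
            raise ValueError("spec1 and spec2 must regulate distinct variables")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")


@dataclass(frozen=True)
class ConstraintSpec:
    """Lateral-boundary and step-width limits for constrained simulation.

    Defaults are a 1.77 m wide treadmill (half-width 0.885 m) and a
    step-width range of mean +/- 5 SD from typical human data
    (-0.0015 m to 0.2554 m; slightly negative, so rare crossover steps
    remain representable).
    """

    z_max: float = 0.885
    w_min: float = -0.0015
    w_max: float = 0.2554
    enforce: bool = True

    def __post_init__(self) -> None:
        if self.z_max <= 0:
            raise ValueError(f"z_max must be > 0, got {self.z_max}")
        if self.w_min >= self.w_max:
            raise ValueError(f"w_min must be < w_max, got [{self.w_min}, {self.w_max}]")


#: Unconstrained pass-through constraints.
UNCONSTRAINED = ConstraintSpec(enforce=False)


@dataclass(frozen=True)
class SimulationConfig:
    """Trial length, replicate count, seed and initial conditions."""

    n_steps: int = 290
    n_trials: int = 30
    seed: int = 0
    first_swing: str = "L"
    z_B0: float = 0.0
    w0: float | None = None  # defaults to the width goal at simulation time

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.first_swing not in ("L", "R"):
            raise ValueError(f"first_swing must be 'L' or 'R', got {self.first_swing!r}")


def control_input(q_n: float, spec: RegulatorSpec) -> float:
    """Optimal control input ``u = -G * (q_n - q*)`` for one step."""
    if not math.isfinite(q_n):
        raise ValueError(f"q_n must be finite, got {q_n}")
    return -spec.gain * (q_n - spec.q_star)


def state_update(q_n: float, u: float, nu_m: float, nu_a: float, spec: RegulatorSpec) -> float:
    """One step of the regulated 1D map.

    ``q_{n+1} = q_n + g*(1 + sigma_m*nu_m)*u + sigma_a*nu_a`` with
    ``nu_m, nu_a`` standard-normal draws from the caller's seeded stream.
    """
    return q_n + spec.g * (1.0 + spec.sigma_m * nu_m) * u + spec.sigma_a * nu_a


def swing_foot_for_target(
    variable: str,
    q_target_next: float,
    stance_z: float,
    swing_side: str,
    z_B_prev: float | None = None,
) -> float:
    """Swing-foot placement that realizes the controller's target.

    Inverts the stepping geometry for the one newly placed foot: given
    the stance foot at ``stance_z`` and the controller's desired next
    value of its variable, there is a unique lateral position for the
    swing foot.  ``z_B_prev`` (the current body position) is needed only
    for the heading variable.
    """
    variable = canonical_variable(variable)
    if swing_side not in ("L", "R"):
        raise ValueError(f"swing_side must be 'L' or 'R', got {swing_side!r}")
    if variable == "w":
        # w = z_R - z_L: placing L below stance R (or R above stance L).
        return stance_z - q_target_next if swing_side == "L" else stance_z + q_target_next
    if variable == "z_B":
        return 2.0 * q_target_next - stance_z
    # heading: z_B_next = z_B_prev + dz_target
    if z_B_prev is None:
        raise ValueError("z_B_prev is required for the heading variable")
    return 2.0 * (z_B_prev + q_target_next) - stance_z


def clamp_to_constraints(
    z_candidate: float,
    stance_z: float,
    swing_side: str,
    constraints: ConstraintSpec,
) -> tuple[float, bool, bool]:
    """Project a candidate placement onto the feasible interval.

    The feasible interval is the intersection of the lateral boundary
    ``[-z_max, +z_max]`` with the placements whose implied step width
    lies in ``[w_min, w_max]``.  Returns ``(z_new, boundary_clamped,
    width_clamped)``; the flags record which limit bound the projection
    (both, on a tie).  Pass-through when ``constraints.enforce`` is off.
    """
    if not constraints.enforce:
        return z_candidate, False, False
    if swing_side == "L":
        # w = stance_z - z  =>  z in [stance_z - w_max, stance_z - w_min]
        w_lo, w_hi = stance_z - constraints.w_max, stance_z - constraints.w_min
    elif swing_side == "R":
        # w = z - stance_z  =>  z in [stance_z + w_min, stance_z + w_max]
        w_lo, w_hi = stance_z + constraints.w_min, stance_z + constraints.w_max
    else:
        raise ValueError(f"swing_side must be 'L' or 'R', got {swing_side!r}")
    lo = max(-constraints.z_max, w_lo)
    hi = min(constraints.z_max, w_hi)
    if lo > hi:
        raise ValueError(
            f"empty feasible interval for swing {swing_side} with stance at "
            f"{stance_z:.4f} m under {constraints}"
        )
    if z_candidate < lo:
        return lo, -constraints.z_max >= w_lo, w_lo >= -constraints.z_max
    if z_candidate > hi:
        return hi, constraints.z_max <= w_hi, w_hi <= constraints.z_max
    return z_candidate, False, False


def _objective_rng(seed: int, variable: str) -> np.random.Generator:
    """Independent noise stream for one objective, keyed by its variable."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_VAR_STREAM_KEY[variable],))
    )


def _simulate(
    objectives: Sequence[tuple[RegulatorSpec, float]],
    config: SimulationConfig,
    constraints: ConstraintSpec,
    meta: dict[str, Any],
) -> FootPlacementTrial:
    """Common simulation engine for uni- and multi-objective regulators."""
    n = config.n_steps
    w_specs = [s for s, _ in objectives if s.variable == "w"]
    w0 = config.w0
    if w0 is None:
        w0 = w_specs[0].q_star if w_specs else DEFAULT_GOALS["w"]

    z_L = np.empty(n)
    z_R = np.empty(n)
    placed = np.empty(n, dtype=object)
    z_L[0] = config.z_B0 - w0 / 2.0
    z_R[0] = config.z_B0 + w0 / 2.0
    placed[0] = "R" if config.first_swing == "L" else "L"

    rngs = [_objective_rng(config.seed, spec.variable) for spec, _ in objectives]

    z_B = config.z_B0
    w = w0
    dz_B = 0.0  # heading undefined before step 1; start at its goal-neutral 0
    n_boundary_clamped = 0
    n_width_clamped = 0

    swing = config.first_swing
    for step in range(1, n):
        stance_z = z_R[step - 1] if swing == "L" else z_L[step - 1]
        current = {"z_B": z_B, "dz_B": dz_B, "w": w}

        placement = 0.0
        for (spec, weight), rng in zip(objectives, rngs):
            q_n = current[spec.variable]
            u = control_input(q_n, spec)
            nu_m, nu_a = rng.standard_normal(2)
            q_next = state_update(q_n, u, nu_m, nu_a, spec)
            cand = swing_foot_for_target(spec.variable, q_next, stance_z, swing, z_B_prev=z_B)
            placement += weight * cand

        placement, b_flag, w_flag = clamp_to_constraints(placement, stance_z, swing, constraints)
        n_boundary_clamped += b_flag
        n_width_clamped += w_flag

        if swing == "L":
            z_L[step], z_R[step] = placement, stance_z
        else:
            z_L[step], z_R[step] = stance_z, placement
        placed[step] = swing

        z_B_new = (z_L[step] + z_R[step]) / 2.0
        dz_B = z_B_new - z_B
        z_B = z_B_new
        w = z_R[step] - z_L[step]
        swing = "L" if swing == "R" else "R"

    meta = dict(meta)
    meta.update(
        seed=config.seed,
        constrained=constraints.enforce,
        n_boundary_clamped=n_boundary_clamped,
        n_width_clamped=n_width_clamped,
    )
    return FootPlacementTrial(z_L=z_L, z_R=z_R, placed_side=placed, meta=meta)


def simulate_uni_objective(
    spec: RegulatorSpec,
    config: SimulationConfig,
    constraints: ConstraintSpec = UNCONSTRAINED,
) -> FootPlacementTrial:
    """Simulate one trial under a single-variable regulator.

    The controlled variable follows its regulated 1D map; all other
    stepping variables drift passively under the alternating-foot
    geometry.  Identical inputs (including seed) give bit-identical
    trials.
    """
    meta = {"model": "uni", "variable": spec.variable}
    return _simulate([(spec, 1.0)], config, constraints, meta)


def simulate_multi_objective(
    spec: MultiObjectiveSpec,
    config: SimulationConfig,
    constraints: ConstraintSpec = UNCONSTRAINED,
) -> FootPlacementTrial:
    """Simulate one trial under a two-objective regulator.

    Each objective independently proposes a swing-foot placement from
    its own regulated map and noise stream; the foot is placed at
    ``(1-rho)*candidate1 + rho*candidate2`` (clamped if constraining),
    and both controllers then observe the realized geometry.
    """
    meta = {
        "model": "multi",
        "variables": (spec.spec1.variable, spec.spec2.variable),
        "rho": spec.rho,
    }
    return _simulate(
        [(spec.spec1, 1.0 - spec.rho), (spec.spec2, spec.rho)], config, constraints, meta
    )


def trial_seeds(seed: int, n_trials: int) -> list[int]:
    """Deterministic, well-separated per-trial seeds derived from one seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n_trials)]


def simulate_trials(
    model: RegulatorSpec | MultiObjectiveSpec,
    config: SimulationConfig,
    constraints: ConstraintSpec = UNCONSTRAINED,
) -> list[FootPlacementTrial]:
    """Simulate ``config.n_trials`` independent trials of one model."""
    sim = simulate_multi_objective if isinstance(model, MultiObjectiveSpec) else simulate_uni_objective
    out = []
    for i, s in enumerate(trial_seeds(config.seed, config.n_trials)):
        cfg = replace(config, seed=s)
        trial = sim(model, cfg, constraints)
        trial.meta["trial_index"] = i
        out.append(trial)
    return out


def violation_rates(trial: FootPlacementTrial, constraints: ConstraintSpec) -> tuple[float, float]:
    """Percentage of steps violating the boundary and step-width limits.

    Boundary: newly placed foot outside ``[-z_max, +z_max]``.  Width:
    resulting step width outside ``[w_min, w_max]``.  Both as percent of
    the trial's steps.
    """
    n = trial.n_steps
    placed = trial.placed_positions()
    w = trial.z_R - trial.z_L
    n_boundary = int(np.sum(np.abs(placed) > constraints.z_max))
    n_width = int(np.sum((w < constraints.w_min) | (w > constraints.w_max)))
    return 100.0 * n_boundary / n, 100.0 * n_width / n


def calibrate_additive_noise(
    target_output_sd: float,
    spec: RegulatorSpec,
    refine: bool = False,
    n_refine: int = 200_000,
    seed: int = 0,
) -> float:
    """Additive-noise SD producing a desired stationary SD of the
    controlled variable.

    Under the regulated map the controlled variable is (neglecting
    multiplicative noise) AR(1) with coefficient ``phi = 1 - g*G``, whose
    stationary SD is ``sigma_a / sqrt(1 - phi^2)``; the closed form is
    inverted.  With ``refine=True`` the result is rescaled by a long
    simulation of the scalar map including multiplicative noise.
    """
    if target_output_sd < 0:
        raise ValueError(f"target_output_sd must be >= 0, got {target_output_sd}")
    phi = 1.0 - spec.g * spec.gain
    if abs(phi) >= 1.0:
        raise ValueError(
            f"controlled variable is non-stationary: |1 - g*G| = {abs(phi):.4f} >= 1"
        )
    sigma_a = target_output_sd * math.sqrt(1.0 - phi * phi)
    if not refine or sigma_a == 0.0:
        return sigma_a
    rng = np.random.default_rng(seed)
    trial_spec = replace(spec, sigma_a=sigma_a)
    q = trial_spec.q_star
    qs = np.empty(n_refine)
    nu = rng.standard_normal((n_refine, 2))
    for i in range(n_refine):
        u = control_input(q, trial_spec)
        q = state_update(q, u, nu[i, 0], nu[i, 1], trial_spec)
        qs[i] = q
    measured = float(np.std(qs[1000:], ddof=1))
    if measured == 0.0:
        return sigma_a
    return sigma_a * target_output_sd / measured
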