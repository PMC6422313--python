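"""Model-selection experiments: parameter sweeps, reference bands, fixtures.

The model-selection logic: simulate a candidate regulator many times,
summarize each trial (variability, DFA exponents, error-correction
slopes), and accept the candidate for a given measure when the mean
simulated value falls inside the reference mean +/- 1 SD band (the range
of values the reference population exhibits).  Reference bands normally
come from analyzed human trials; a synthetic reference fixture — 65
trials of 290 steps from the constrained 93%-width / 7%-position
multi-objective model, the configuration known to reproduce human
stepping dynamics — stands in when human data are not available.

The default sensitivity grid crosses mixing proportions
``rho in {0.89, 0.91, 0.93, 0.95, 0.97}`` with five parameter variants
(baseline; gamma/alpha = 0 and 0.2; additive noise scaled by 0.9 and
1.1), 25 conditions in all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fluctuation import SUMMARY_COLUMNS, summarize_trial
from .regulators import (
    BASELINE_GAMMA_OVER_ALPHA,
    ConstraintSpec,
    MultiObjectiveSpec,
    RegulatorSpec,
    SimulationConfig,
    simulate_trials,
    violation_rates,
)
from .geometry import write_trial

__all__ = [
    "ReferenceBands",
    "baseline_position_width_model",
    "default_sweep_grid",
    "run_parameter_sweep",
    "compare_to_reference",
    "stats_frame",
    "generate_reference_fixture",
]

#: z-critical value for the 95% confidence interval on a mean.
_Z95 = 1.959963984540054


@dataclass
class ReferenceBands:
    """Mean +/- 1 SD acceptance band per summary measure."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.mean) != set(self.sd):
            raise ValueError("mean and sd must cover the same measures")
        neg = [m for m, s in self.sd.items() if s < 0]
        if neg:
            raise ValueError(f"negative band SD for {neg[0]!r}")

    @classmethod
    def from_stats(cls, stats: pd.DataFrame) -> "ReferenceBands":
        """Bands from a per-trial stats table (one row per trial)."""
        cols = [c for c in SUMMARY_COLUMNS if c in stats.columns]
        return cls(
            mean={c: float(stats[c].mean()) for c in cols},
            sd={c: float(stats[c].std(ddof=1)) for c in cols},
        )

    def to_frame(self) -> pd.DataFrame:
        measures = sorted(self.mean)
        return pd.DataFrame(
            {
                "measure": measures,
                "mean": [self.mean[m] for m in measures],
                "sd": [self.sd[m] for m in measures],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ReferenceBands":
        df = pd.read_csv(path)
        for col in ("measure", "mean", "sd"):
            if col not in df.columns:
                raise ValueError(f"bands file {path} is missing column {col!r}")
        return cls(
            mean=dict(zip(df["measure"], df["mean"].astype(float))),
            sd=dict(zip(df["measure"], df["sd"].astype(float))),
        )


def baseline_position_width_model(
    rho: float = 0.93,
    gamma_over_alpha: float = BASELINE_GAMMA_OVER_ALPHA,
    sigma_a_scale: float = 1.0,
) -> MultiObjectiveSpec:
    """The headline position–step-width mixture at baseline parameters."""
    pos = RegulatorSpec("z_B", gamma_over_alpha=gamma_over_alpha)
    wid = RegulatorSpec("w", gamma_over_alpha=gamma_over_alpha)
    if sigma_a_scale != 1.0:
        pos = replace(pos, sigma_a=pos.sigma_a * sigma_a_scale)
        wid = replace(wid, sigma_a=wid.sigma_a * sigma_a_scale)
    return MultiObjectiveSpec(spec1=pos, spec2=wid, rho=rho)


def default_sweep_grid() -> list[dict]:
    """The 5 x 5 sensitivity grid: rho 0.89..0.97 x parameter variants."""
    variants = [
        {"label": "baseline", "gamma_over_alpha": BASELINE_GAMMA_OVER_ALPHA, "sigma_a_scale": 1.0},
        {"label": "gamma0.0", "gamma_over_alpha": 0.0, "sigma_a_scale": 1.0},
        {"label": "gamma0.2", "gamma_over_alpha": 0.2, "sigma_a_scale": 1.0},
        {"label": "sigma0.9", "gamma_over_alpha": BASELINE_GAMMA_OVER_ALPHA, "sigma_a_scale": 0.9},
        {"label": "sigma1.1", "gamma_over_alpha": BASELINE_GAMMA_OVER_ALPHA, "sigma_a_scale": 1.1},
    ]
    grid = []
    for rho in (0.89, 0.91, 0.93, 0.95, 0.97):
        for v in variants:
            grid.append({"rho": round(rho, 2), **v})
    return grid


def stats_frame(trials) -> pd.DataFrame:
    """Per-trial summary statistics as a DataFrame (one row per trial)."""
    return pd.DataFrame([summarize_trial(t).as_dict() for t in trials])


def run_parameter_sweep(
    grid: list[dict] | None = None,
    config: SimulationConfig | None = None,
    constraints: ConstraintSpec | None = None,
) -> pd.DataFrame:
    """Simulate every grid condition and aggregate its dependent measures.

    For each condition, ``config.n_trials`` trials are simulated and the
    summary measures aggregated as mean and 95% CI half-width
    (1.96 * SEM) across trials.  Violation percentages against the
    constraint limits are reported both for the simulated trials and for
    unconstrained twins (same seeds, no clamping), which show whether
    the condition is feasible without enforcement.  Deterministic for a
    given seed.
    """
    if grid is None:
        grid = default_sweep_grid()
    if not grid:
        raise ValueError("empty sweep grid")
    if config is None:
        config = SimulationConfig()
    if constraints is None:
        constraints = ConstraintSpec()
    unconstrained = replace(constraints, enforce=False)

    rows = []
    for cond in grid:
        model = baseline_position_width_model(
            rho=cond["rho"],
            gamma_over_alpha=cond.get("gamma_over_alpha", BASELINE_GAMMA_OVER_ALPHA),
            sigma_a_scale=cond.get("sigma_a_scale", 1.0),
        )
        trials = simulate_trials(model, config, constraints)
        twins = simulate_trials(model, config, unconstrained)
        stats = stats_frame(trials)
        row: dict = {
            "rho": cond["rho"],
            "label": cond.get("label", ""),
            "gamma_over_alpha": cond.get("gamma_over_alpha", BASELINE_GAMMA_OVER_ALPHA),
            "sigma_a_scale": cond.get("sigma_a_scale", 1.0),
            "constrained": constraints.enforce,
            "n_trials": config.n_trials,
        }
        for c in SUMMARY_COLUMNS:
            vals = stats[c].to_numpy()
            row[f"mean_{c}"] = float(np.mean(vals))
            row[f"ci_{c}"] = float(_Z95 * np.std(vals, ddof=1) / np.sqrt(len(vals)))
        viol = np.array([violation_rates(t, constraints) for t in trials])
        viol_u = np.array([violation_rates(t, constraints) for t in twins])
        row["pct_boundary"] = float(viol[:, 0].mean())
        row["pct_width"] = float(viol[:, 1].mean())
        row["pct_boundary_unconstrained"] = float(viol_u[:, 0].mean())
        row["pct_width_unconstrained"] = float(viol_u[:, 1].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_to_reference(row: Mapping, bands: ReferenceBands) -> dict[str, bool]:
    """Per-measure verdicts for one sweep row against reference bands.

    A measure passes when ``|mean_sim - mean_ref| <= sd_ref``.  The row
    may be a sweep-table row (``mean_<measure>`` columns) or a plain
    mapping of measure -> value.
    """
    verdicts = {}
    for measure in sorted(bands.mean):
        key = f"mean_{measure}" if f"mean_{measure}" in row else measure
        if key not in row:
            raise ValueError(f"row is missing measure {measure!r}")
        verdicts[measure] = bool(
            abs(float(row[key]) - bands.mean[measure]) <= bands.sd[measure]
        )
    return verdicts


def generate_reference_fixture(
    seed: int,
    out_dir=None,
    n_trials: int = 65,
    n_steps: int = 290,
) -> tuple[list, ReferenceBands]:
    """Synthetic stand-in for a human reference data set.

    Simulates ``n_trials`` trials of ``n_steps`` steps from the
    constrained baseline rho = 0.93 position–width model — the
    configuration that reproduces human lateral stepping dynamics
    (strongly persistent position, anti-persistent heading, weakly
    persistent step width) — and computes reference bands from their
    summary statistics.  If ``out_dir`` is given, writes one trial file
    per trial plus ``stats.csv`` and ``bands.csv``.
    """
    model = baseline_position_width_model()
    config = SimulationConfig(n_steps=n_steps, n_trials=n_trials, seed=seed)
    trials = simulate_trials(model, config, ConstraintSpec())
    stats = stats_frame(trials)
    bands = ReferenceBands.from_stats(stats)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(trials):
            write_trial(t, out_dir / f"trial_{i:03d}.csv")
        stats.to_csv(out_dir / "stats.csv", index=False)
        bands.to_csv(out_dir / "bands.csv")
    return trials, bands
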