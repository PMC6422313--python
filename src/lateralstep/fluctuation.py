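"""Dependent measures for stepping time series.

Three complementary analyses quantify how a stepping variable fluctuates
from step to step:

* variability — the sample standard deviation of the series;
* temporal structure — the detrended fluctuation analysis (DFA) scaling
  exponent ``alpha``: ``alpha ~ 1/2`` for uncorrelated fluctuations,
  ``alpha > 1/2`` statistical persistence, ``alpha < 1/2``
  anti-persistence, ``alpha ~ 3/2`` Brownian-like (integrated white
  noise).  Tightly regulated variables show ``alpha ~ 1/2`` or below;
  unregulated ones drift with ``alpha >> 1/2``;
* direct error correction — the least-squares slope of the next-step
  change ``dq_{n+1} = q_{n+1} - q_n`` against the current deviation
  ``q'_n = q_n - mean(q)``.  A slope near -1 with high r² indicates
  strong proportional single-step correction; near 0 with low r², no
  direct correction (for an AR(1) series with coefficient ``phi`` the
  slope converges to ``phi - 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import FootPlacementTrial, derive_state_series

__all__ = [
    "DFAResult",
    "DirectControlResult",
    "SummaryStats",
    "dfa_alpha",
    "series_sd",
    "direct_control_regression",
    "summarize_trial",
]


@dataclass
class DFAResult:
    """DFA scaling exponent with its log-log fit."""

    scales: np.ndarray  # segment lengths j, strictly increasing
    F: np.ndarray  # RMS detrended fluctuation per scale (input units)
    alpha: float  # scaling exponent (log-log slope)
    fit_r2: float  # goodness of the log F vs log j fit


@dataclass
class DirectControlResult:
    """Error-correction regression of dq_{n+1} on q'_n."""

    slope: float
    intercept: float
    r2: float


def _dfa_scales(n: int, n_scales: int, spacing: str) -> np.ndarray:
    max_scale = n // 4
    if spacing == "linear":
        raw = np.linspace(4, max_scale, n_scales)
    elif spacing == "log":
        raw = np.geomspace(4, max_scale, n_scales)
    else:
        raise ValueError(f"spacing must be 'linear' or 'log', got {spacing!r}")
    return np.unique(np.rint(raw).astype(int))


def dfa_alpha(x, n_scales: int = 50, spacing: str = "linear") -> DFAResult:
    """Detrended fluctuation analysis scaling exponent of a series.

    The series is mean-centered and cumulatively summed; at each segment
    length ``j`` (``n_scales`` values evenly distributed between 4 and
    ``N/4``, linear spacing by default) the profile is split into
    ``floor(N/j)`` non-overlapping segments anchored at the start (tail
    remainder discarded), a least-squares line is removed from each
    segment, and ``F(j)`` is the RMS residual over all covered points.
    ``alpha`` is the least-squares slope of ``log F(j)`` vs ``log j``.

    Raises ``ValueError`` for series shorter than 16 points, non-finite
    input, or a (locally) constant series for which some ``F(j) = 0``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 16:
        raise ValueError(f"DFA needs at least 16 points, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("DFA input must be finite")
    if np.ptp(x) == 0.0:
        raise ValueError("DFA is undefined for a constant series")

    y = np.cumsum(x - x.mean())
    scales = _dfa_scales(n, n_scales, spacing)
    F = np.empty(scales.shape[0])
    for k, j in enumerate(scales):
        m = n // j
        seg = y[: m * j].reshape(m, j)
        t = np.arange(j, dtype=float)
        t_c = t - t.mean()
        denom = np.sum(t_c * t_c)
        seg_mean = seg.mean(axis=1, keepdims=True)
        slope = (seg - seg_mean) @ t_c / denom
        resid = seg - seg_mean - slope[:, None] * t_c
        F[k] = math.sqrt(float(np.mean(resid * resid)))
    if np.any(F == 0.0):
        raise ValueError("DFA fluctuation is zero at some scale (degenerate series)")

    log_j = np.log(scales.astype(float))
    log_F = np.log(F)
    fit = stats.linregress(log_j, log_F)
    return DFAResult(scales=scales, F=F, alpha=float(fit.slope), fit_r2=float(fit.rvalue**2))


def series_sd(x) -> float:
    """Sample standard deviation (n-1 denominator) of a series."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError(f"need at least 2 points for an SD, got {x.shape[0]}")
    return float(np.std(x, ddof=1))


def direct_control_regression(q) -> DirectControlResult:
    """Regress the next-step change on the current deviation from the mean.

    OLS fit of ``dq_{n+1} = q_{n+1} - q_n`` against
    ``q'_n = q_n - mean(q)`` over ``n = 0 .. N-2``.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[0] < 3:
        raise ValueError(f"need at least 3 points, got {q.shape[0]}")
    q_dev = q[:-1] - q.mean()
    dq = np.diff(q)
    if np.ptp(q_dev) == 0.0:
        raise ValueError("zero variance in q' (constant series)")
    fit = stats.linregress(q_dev, dq)
    return DirectControlResult(
        slope=float(fit.slope), intercept=float(fit.intercept), r2=float(fit.rvalue**2)
    )


# Measures reported per trial; degenerate analyses (e.g. a constant series
# from a noise-free simulation) are reported as NaN.
SUMMARY_COLUMNS = (
    "sd_zB", "sd_dzB", "sd_w",
    "alpha_zB", "alpha_dzB", "alpha_w",
    "slope_zB", "slope_dzB", "slope_w",
    "r2_zB", "r2_dzB", "r2_w",
    "sd_zL", "sd_zR", "alpha_zL", "alpha_zR",
)


@dataclass
class SummaryStats:
    """Per-variable variability, DFA exponent and error-correction fit.

    Covers body position (zB), heading (dzB) and step width (w) with
    sd / alpha / slope / r2 each, plus sd and alpha of the individual
    left (zL) and right (zR) foot-placement series.
    """

    sd_zB: float
    sd_dzB: float
    sd_w: float
    alpha_zB: float
    alpha_dzB: float
    alpha_w: float
    slope_zB: float
    slope_dzB: float
    slope_w: float
    r2_zB: float
    r2_dzB: float
    r2_w: float
    sd_zL: float
    sd_zR: float
    alpha_zL: float
    alpha_zR: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in SUMMARY_COLUMNS}


def _maybe(fn, x) -> float:
    try:
        return fn(x)
    except ValueError:
        return math.nan


def summarize_trial(trial: FootPlacementTrial) -> SummaryStats:
    """All dependent measures for one trial.

    Heading analyses use the length-(N-1) series (step 0 undefined).
    Degenerate series (constant, e.g. from noise-free simulations) yield
    NaN for the affected measures rather than an error.
    """
    if trial.n_steps < 16:
        raise ValueError(f"need at least 16 steps to summarize, got {trial.n_steps}")
    state = derive_state_series(trial)
    vals: dict[str, float] = {}
    for tag, series in (("zB", state.z_B), ("dzB", state.dz_B), ("w", state.w)):
        vals[f"sd_{tag}"] = _maybe(series_sd, series)
        vals[f"alpha_{tag}"] = _maybe(lambda s: dfa_alpha(s).alpha, series)
        reg = None
        try:
            reg = direct_control_regression(series)
        except ValueError:
            pass
        vals[f"slope_{tag}"] = reg.slope if reg else math.nan
        vals[f"r2_{tag}"] = reg.r2 if reg else math.nan
    for tag, series in (("zL", trial.z_L), ("zR", trial.z_R)):
        vals[f"sd_{tag}"] = _maybe(series_sd, series)
        vals[f"alpha_{tag}"] = _maybe(lambda s: dfa_alpha(s).alpha, series)
    return SummaryStats(**vals)
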