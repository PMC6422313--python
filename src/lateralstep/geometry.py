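"""Domain types and exact linear maps for lateral stepping trials.

A walking trial is a sequence of lateral (frontal-plane) foot placements,
one new placement per step, alternating feet.  From the left/right foot
placement series ``z_L``/``z_R`` three control-relevant variables are
derived:

* lateral body position ``z_B = (z_L + z_R) / 2`` (midpoint of the feet,
  a proxy for center-of-mass location),
* heading ``dz_B[n] = z_B[n] - z_B[n-1]`` (step-to-step change in body
  position, a proxy for lateral speed/direction; undefined at step 0),
* step width ``w = z_R - z_L`` (signed: negative means a crossover step).

The map ``(z_L, z_R) <-> (z_B, w)`` is an exact, invertible linear
change of coordinates; :func:`feet_from_state` is the inverse of
:func:`derive_state_series` restricted to ``(z_B, w)``.

Coordinate convention: +z is the direction for which ``z_R > z_L`` in
normal stance, origin at the centerline of the walking path.  All
quantities are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "FootPlacementTrial",
    "StateSeries",
    "derive_state_series",
    "feet_from_state",
    "read_trial",
    "write_trial",
    "write_state_series",
]

_SIDES = ("L", "R")


@dataclass
class FootPlacementTrial:
    """Per-step left/right lateral foot placements for one walking trial.

    Parameters
    ----------
    z_L, z_R
        Lateral positions of the left and right foot at each step, in
        meters.  Both feet have a defined position every step; only the
        foot named in ``placed_side`` was newly placed on that step, the
        other is carried over from the previous step.
    placed_side
        Which foot was newly placed at each step, ``"L"`` or ``"R"``,
        strictly alternating.
    meta
        Free-form provenance (seed, regulator configuration, clamp
        counts, ...).  Not validated.
    """

    z_L: np.ndarray
    z_R: np.ndarray
    placed_side: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_L = np.asarray(self.z_L, dtype=float)
        self.z_R = np.asarray(self.z_R, dtype=float)
        self.placed_side = np.asarray(self.placed_side, dtype=object)
        n = self.z_L.shape[0]
        if self.z_R.shape[0] != n or self.placed_side.shape[0] != n:
            raise ValueError(
                f"z_L, z_R and placed_side must have equal length; got "
                f"{n}, {self.z_R.shape[0]}, {self.placed_side.shape[0]}"
            )
        if n < 2:
            raise ValueError(f"a trial needs at least 2 steps, got {n}")
        for name, arr in (("z_L", self.z_L), ("z_R", self.z_R)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValueError(f"non-finite {name} at step {bad[0]}")
        bad_side = [s for s in self.placed_side if s not in _SIDES]
        if bad_side:
            raise ValueError(f"placed_side entries must be 'L' or 'R', got {bad_side[0]!r}")
        same = np.flatnonzero(self.placed_side[1:] == self.placed_side[:-1])
        if same.size:
            i = int(same[0])
            raise ValueError(
                f"placed_side must alternate: steps {i} and {i + 1} are both "
                f"{self.placed_side[i]!r}"
            )

    @property
    def n_steps(self) -> int:
        return self.z_L.shape[0]

    @property
    def step_index(self) -> np.ndarray:
        return np.arange(self.n_steps)

    def placed_positions(self) -> np.ndarray:
        """Lateral position of the newly placed foot at each step."""
        return np.where(self.placed_side == "L", self.z_L, self.z_R)


@dataclass
class StateSeries:
    """Derived stepping variables: body position, heading, step width.

    ``z_B`` and ``w`` have length N; ``dz_B`` has length N-1 (its value
    at step 0 is undefined and omitted — analyses consume the shortened
    series; ``dz_B[k]`` is the heading at step ``k + 1``).
    """

    z_B: np.ndarray
    dz_B: np.ndarray
    w: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.z_B.shape[0]


def derive_state_series(trial: FootPlacementTrial) -> StateSeries:
    """Compute body position, heading and step width from foot placements.

    Exact arithmetic: ``z_B = (z_L + z_R)/2``, ``w = z_R - z_L``,
    ``dz_B = diff(z_B)``.
    """
    z_B = (trial.z_L + trial.z_R) / 2.0
    w = trial.z_R - trial.z_L
    dz_B = np.diff(z_B)
    return StateSeries(z_B=z_B, dz_B=dz_B, w=w)


def feet_from_state(z_B, w) -> tuple[np.ndarray, np.ndarray]:
    """Invert the geometry: recover foot placements from (z_B, w).

    ``z_L = z_B - w/2``, ``z_R = z_B + w/2``.  Bit-exact inverse of
    :func:`derive_state_series` restricted to (z_B, w).
    """
    z_B = np.asarray(z_B, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(z_B)) and np.all(np.isfinite(w))):
        raise ValueError("z_B and w must be finite")
    half = w / 2.0
    return z_B - half, z_B + half


_TRIAL_COLUMNS = ("step", "side", "z_L", "z_R")


def write_trial(trial: FootPlacementTrial, path) -> None:
    """Write a trial to delimited text (``step,side,z_L,z_R``; meters).

    Full floating precision (round-trips losslessly through
    :func:`read_trial`).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("step,side,z_L,z_R\n")
        for i in range(trial.n_steps):
            fh.write(
                f"{i},{trial.placed_side[i]},"
                f"{float(trial.z_L[i])!r},{float(trial.z_R[i])!r}\n"
            )


def read_trial(path) -> FootPlacementTrial:
    """Read a trial file written by :func:`write_trial`.

    Raises ``ValueError`` naming the missing column, the offending row
    for malformed values, or the steps violating side alternation.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"side": str}, float_precision="round_trip")
    for col in _TRIAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trial file {path} is missing column {col!r}")
    for col in ("z_L", "z_R"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            raise ValueError(
                f"trial file {path}: malformed {col} value in row {int(bad[0])}"
            )
    return FootPlacementTrial(
        z_L=df["z_L"].to_numpy(dtype=float),
        z_R=df["z_R"].to_numpy(dtype=float),
        placed_side=df["side"].to_numpy(dtype=object),
        meta={"source": str(path)},
    )


def write_state_series(state: StateSeries, path) -> None:
    """Write derived variables (``step,z_B,dz_B,w``; dz_B blank on row 0)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("step,z_B,dz_B,w\n")
        for i in range(state.n_steps):
            dz = "" if i == 0 else repr(float(state.dz_B[i - 1]))
            fh.write(f"{i},{float(state.z_B[i])!r},{dz},{float(state.w[i])!r}\n")
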