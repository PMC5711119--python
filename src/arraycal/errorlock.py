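"""Propagation-error model, narrow-field error-locking, and correction.

Ratio-chain reconstruction multiplies one shifted/unshifted ratio per
step, so a small systematic per-step error accumulates geometrically
toward the array edges.  Two per-step components are modelled:

* ``e1`` -- inter-measurement output variation.  Alone it tilts the
  reconstructed profile: the negative side rises while the positive side
  falls (or vice versa).
* ``e2`` -- array positioning error, folded into a single average factor
  although physically it scales with the local profile gradient.  Alone
  it moves both sides the same way, flattening or sharpening the profile.

The distorted profile relates to the true one by

    RNOR'(X) = RNOR(X) * (1 + e1 - e2)^(-X)   for X < 0
    RNOR'(X) = RNOR(X) / (1 + e1 + e2)^X      for X > 0

Error-locking estimates (e1, e2) by anchoring the reconstructed profile
at two positions A < 0 < C where the true relative profile is known
independently from equal-fluence narrow-field triad exposures, then
inverts the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ArrayGeometry, GridSpec
from .reconstruction import (
    NormalizedProfile1D,
    ReconstructionError,
    readings_on_grid,
)

__all__ = [
    "ErrorLockError",
    "ErrorEstimate",
    "LockingTriad",
    "propagation_factor",
    "apply_propagation_error",
    "correct_profile",
    "triad_relative_sensitivities",
    "anchor_points",
    "solve_errors",
    "estimate_axis_errors",
]


class ErrorLockError(ValueError):
    """Invalid error parameters or unusable anchors."""


@dataclass(frozen=True)
class ErrorEstimate:
    """Per-step error components of one axis, as dimensionless fractions.

    ``diagnostics`` retains the per-row (or per-column) estimates behind
    the aggregate and the number of rows used.
    """

    axis: str
    e1: float
    e2: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_bounds(self.e1, self.e2)

    @property
    def e1_pct(self) -> float:
        return 100.0 * self.e1

    @property
    def e2_pct(self) -> float:
        return 100.0 * self.e2


def _check_bounds(e1: float, e2: float) -> None:
    if not (1.0 + e1 - e2 > 0.0 and 1.0 + e1 + e2 > 0.0):
        raise ErrorLockError(
            f"error components out of bounds: 1+e1-e2 and 1+e1+e2 must be "
            f"positive (e1={e1}, e2={e2})"
        )


def propagation_factor(local_error: float, n_steps: int) -> float:
    """Accumulated multiplicative factor (1 + local_error)**n_steps."""
    if 1.0 + local_error <= 0.0:
        raise ErrorLockError(f"1 + local_error must be positive, got {local_error}")
    if n_steps < 0:
        raise ErrorLockError("n_steps must be >= 0")
    return (1.0 + local_error) ** n_steps


def _distort(values: np.ndarray, indices: np.ndarray, e1: float, e2: float) -> np.ndarray:
    out = values.copy()
    neg, pos = indices < 0, indices > 0
    # the model acts through the combined per-step factors, so sum the
    # components first: e1 = e2 then cancels exactly on the negative side
    out[neg] = values[neg] * (1.0 + (e1 - e2)) ** (-indices[neg])
    out[pos] = values[pos] / (1.0 + (e1 + e2)) ** indices[pos]
    return out


def apply_propagation_error(
    profile: NormalizedProfile1D, e1: float, e2: float
) -> NormalizedProfile1D:
    """Forward error model: distort an ideal profile by per-step (e1, e2)."""
    _check_bounds(e1, e2)
    return replace(profile, values=_distort(profile.values, profile.indices, e1, e2))


def correct_profile(
    profile: NormalizedProfile1D, estimate: ErrorEstimate
) -> NormalizedProfile1D:
    """Exact inverse of the forward error model under ``estimate``."""
    if estimate.axis != profile.axis:
        raise ErrorLockError(
            f"estimate is for the {estimate.axis} axis, profile is {profile.axis}"
        )
    values = profile.values.copy()
    idx = profile.indices
    neg, pos = idx < 0, idx > 0
    values[neg] = profile.values[neg] / (
        1.0 + (estimate.e1 - estimate.e2)
    ) ** (-idx[neg])
    values[pos] = profile.values[pos] * (
        1.0 + (estimate.e1 + estimate.e2)
    ) ** idx[pos]
    return replace(profile, values=values)


@dataclass
class LockingTriad:
    """Three equal-fluence narrow-field exposures at positions A < 0 < C.

    Each exposure shifts the array so that the detectors at the probed
    position sit under the center of the narrow strip: the A exposure is
    shifted by -A steps, B by 0, C by -C.  All three share geometry and
    field, so A, B and C detectors receive identical fluence and their
    reading ratios are pure sensitivity ratios.
    """

    a: object
    b: object
    c: object
    position_a: int
    position_c: int
    axis: str

    def __post_init__(self) -> None:
        if self.axis not in ("lateral", "longitudinal"):
            raise ErrorLockError(f"unknown axis {self.axis!r}")
        if not (self.position_a < 0 < self.position_c):
            raise ErrorLockError(
                f"triad positions must satisfy A < 0 < C, got "
                f"({self.position_a}, {self.position_c})"
            )
        for m, pos in ((self.a, self.position_a), (self.b, 0), (self.c, self.position_c)):
            step = m.shift_steps[0] if self.axis == "lateral" else m.shift_steps[1]
            if step != -pos:
                raise ErrorLockError(
                    f"the exposure probing position {pos} must be shifted by "
                    f"{-pos} steps along the {self.axis} axis, got {step}"
                )


def _probe(values: np.ndarray, grid: GridSpec, axis: str, position: int) -> np.ndarray:
    """Readings of the probed row/column as a vector over the other axis."""
    if axis == "lateral":
        return values[:, grid.col_of(position)]
    return values[grid.row_of(position), :]


def triad_relative_sensitivities(
    triad: LockingTriad, geometry: ArrayGeometry, grid: GridSpec
) -> dict[str, np.ndarray]:
    """Per-row sensitivity ratios S(A)/S(B) and S(C)/S(B) from the triad.

    Returns vectors over the non-scanned axis (grid row indices for a
    lateral triad).  NaN where either detector is missing.
    """
    ga = readings_on_grid(triad.a, geometry, grid)
    gb = readings_on_grid(triad.b, geometry, grid)
    gc = readings_on_grid(triad.c, geometry, grid)
    num_a = _probe(ga, grid, triad.axis, triad.position_a)
    num_c = _probe(gc, grid, triad.axis, triad.position_c)
    den = _probe(gb, grid, triad.axis, 0)
    for name, v in (("A", num_a), ("C", num_c), ("B", den)):
        if np.any(v[np.isfinite(v)] <= 0):
            raise ReconstructionError(f"non-positive reading in triad exposure {name}")
    with np.errstate(invalid="ignore"):
        return {"a": num_a / den, "c": num_c / den}


def anchor_points(
    mc, rel_sens: dict[str, np.ndarray], triad: LockingTriad,
    geometry: ArrayGeometry, grid: GridSpec,
) -> dict[str, np.ndarray]:
    """Sensitivity-corrected wide-field profile values at the anchors.

    RNOR(A, row) = [MC(A, row)/MC(0, row)] / [S(A, row)/S(0, row)], per row
    along the non-scanned axis; likewise at C.  These are the "true"
    normalized profile values the reconstruction is locked to.
    """
    mc_g = readings_on_grid(mc, geometry, grid)
    if np.any(mc_g[np.isfinite(mc_g)] <= 0):
        raise ReconstructionError("non-positive reading in the wide-field measurement")
    center = _probe(mc_g, grid, triad.axis, 0)
    with np.errstate(invalid="ignore"):
        return {
            "a": _probe(mc_g, grid, triad.axis, triad.position_a) / center / rel_sens["a"],
            "c": _probe(mc_g, grid, triad.axis, triad.position_c) / center / rel_sens["c"],
        }


def solve_errors(
    reconstructed: NormalizedProfile1D,
    anchors: dict[str, float],
    position_a: int,
    position_c: int,
) -> tuple[float, float]:
    """Closed-form inversion of the error model at two anchors.

    With u = (RNOR'(A)/RNOR(A))**(1/(-A)) - 1 = e1 - e2 and
    v = (RNOR(C)/RNOR'(C))**(1/C) - 1 = e1 + e2, the components are
    e1 = (u + v)/2 and e2 = (v - u)/2.
    """
    if not (position_a < 0 < position_c):
        raise ErrorLockError("anchor positions must satisfy A < 0 < C")
    ra, rc = anchors["a"], anchors["c"]
    pa, pc = reconstructed.value(position_a), reconstructed.value(position_c)
    if any(not math.isfinite(v) or v <= 0 for v in (ra, rc, pa, pc)):
        raise ErrorLockError(
            f"anchors and reconstructed values must be positive and finite "
            f"(anchors=({ra}, {rc}), reconstructed=({pa}, {pc}))"
        )
    u = (pa / ra) ** (1.0 / (-position_a)) - 1.0
    v = (rc / pc) ** (1.0 / position_c) - 1.0
    return (u + v) / 2.0, (v - u) / 2.0


def estimate_axis_errors(
    rows: dict[int, NormalizedProfile1D],
    anchors: dict[str, np.ndarray],
    grid: GridSpec,
    triad: LockingTriad,
) -> ErrorEstimate:
    """Per-row closed-form solves aggregated by unweighted mean.

    Rows whose chains do not reach both anchors (or whose anchors fall on
    masked detectors) are skipped and recorded in the diagnostics.
    """
    other = grid.y_indices if triad.axis == "lateral" else grid.x_indices
    per_row: dict[int, tuple[float, float]] = {}
    skipped: list[int] = []
    for j, idx in enumerate(other):
        row = rows.get(int(idx))
        ra, rc = float(anchors["a"][j]), float(anchors["c"][j])
        if row is None or not (
            math.isfinite(ra)
            and math.isfinite(rc)
            and math.isfinite(row.value(triad.position_a))
            and math.isfinite(row.value(triad.position_c))
        ):
            if row is not None:
                skipped.append(int(idx))
            continue
        per_row[int(idx)] = solve_errors(
            row, {"a": ra, "c": rc}, triad.position_a, triad.position_c
        )
    if not per_row:
        raise ErrorLockError("no row provides both anchors; cannot estimate errors")
    e1s = np.array([v[0] for v in per_row.values()])
    e2s = np.array([v[1] for v in per_row.values()])
    return ErrorEstimate(
        axis=triad.axis,
        e1=float(e1s.mean()),
        e2=float(e2s.mean()),
        diagnostics={
            "per_row": per_row,
            "n_rows": len(per_row),
            "skipped_rows": skipped,
            "e1_sd": float(e1s.std(ddof=1)) if len(per_row) > 1 else 0.0,
            "e2_sd": float(e2s.std(ddof=1)) if len(per_row) > 1 else 0.0,
        },
    )
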