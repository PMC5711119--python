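"""Sensitivity-free beam-profile reconstruction.

Two routes are provided:

* the iterative ratio-chain method: each 1D profile value is a telescoping
  product of shifted/unshifted reading ratios, in which the per-detector
  sensitivities cancel exactly;
* the noniterative narrow-field-scan reference (after Greer's 1D method,
  extended to 2D): relative sensitivities along an axis are read off
  equal-fluence narrow-field exposures, and the wide-field reading divided
  by them gives the profile point-by-point, with no error propagation.

Products are evaluated as exponentials of sums of log-ratios so the two
chain directions are treated symmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ArrayGeometry, GridSpec

__all__ = [
    "ReconstructionError",
    "NormalizedProfile1D",
    "NormalizedProfile2D",
    "readings_on_grid",
    "lateral_row_profile",
    "longitudinal_profile",
    "compose_2d",
    "IterativeReconstruction",
    "reconstruct_2dbp",
    "reconstruct_greer",
]


class ReconstructionError(ValueError):
    """Unusable readings or inconsistent measurement roles."""


@dataclass
class NormalizedProfile1D:
    """A relative 1D beam profile on signed grid indices, unity at index 0.

    ``axis`` is the direction the indices run along; ``index`` is the fixed
    coordinate of the row/column the profile belongs to.  ``values`` is
    aligned with indices ``start .. start + len(values) - 1``; NaN marks
    indices whose ratio chain was truncated by a missing detector.
    """

    axis: str
    index: int
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in ("lateral", "longitudinal"):
            raise ReconstructionError(f"unknown axis {self.axis!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not (self.start <= 0 < self.start + self.values.size):
            raise ReconstructionError("profile must cover index 0")
        if self.values[-self.start] != 1.0:
            raise ReconstructionError("profile must be exactly 1 at index 0")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite <= 0):
            raise ReconstructionError("profile values must be positive")

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.values.size)

    def value(self, i: int) -> float:
        j = int(i) - self.start
        if not 0 <= j < self.values.size:
            return math.nan
        return float(self.values[j])


@dataclass
class NormalizedProfile2D:
    """Relative 2D beam profile on a reconstruction grid, unity at (0, 0)."""

    grid: GridSpec
    values: np.ndarray  # (ny, nx), NaN where undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ReconstructionError(
                f"values shape {self.values.shape} != grid ({self.grid.ny}, {self.grid.nx})"
            )
        if self.value(0, 0) != 1.0:
            raise ReconstructionError("profile must be exactly 1 at the origin")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite <= 0):
            raise ReconstructionError("profile values must be positive")

    def value(self, x_index: int, y_index: int) -> float:
        return float(self.values[self.grid.row_of(y_index), self.grid.col_of(x_index)])


def readings_on_grid(measurement, geometry: ArrayGeometry, grid: GridSpec) -> np.ndarray:
    """(ny, nx) matrix of the readings of reconstruction-grid detectors.

    NaN where no unmasked detector coincides with the grid node.  Grid
    indices refer to unshifted detector positions (the detector that sits at
    node (X, Y) when the array is unshifted), regardless of the
    measurement's shift.
    """
    det = geometry.grid_detector_map(grid)
    out = np.full((grid.ny, grid.nx), np.nan)
    has = det[..., 0] >= 0
    out[has] = measurement.readings[det[has, 0], det[has, 1]]
    return out


def _chain(
    numer: np.ndarray, denom: np.ndarray, start: int, axis: str, index: int
) -> NormalizedProfile1D:
    """Bidirectional telescoping ratio chain normalized at grid index 0.

    For negative indices the forward product of numer/denom ratios is
    accumulated; for positive indices the reciprocal product.  The chain
    truncates at a missing (NaN) reading; a non-positive finite reading
    inside a chain is an error.
    """
    n = numer.size
    if denom.size != n:
        raise ReconstructionError("measurement rows cover different grid indices")
    i0 = -start
    if not 0 <= i0 < n:
        raise ReconstructionError("grid index 0 not covered")
    logr = np.full(n, np.nan)
    for j in range(n):
        a, b = numer[j], denom[j]
        if np.isnan(a) or np.isnan(b):
            continue
        if a <= 0 or b <= 0:
            raise ReconstructionError(
                f"non-positive reading at {axis} grid index {start + j} "
                f"(row/col {index}): shifted={a!r}, unshifted={b!r}"
            )
        logr[j] = math.log(a) - math.log(b)
    out = np.full(n, np.nan)
    out[i0] = 1.0
    # X < 0: RNOR(X) = prod_{i=1..-X} numer(X+i)/denom(X+i) -> ratios at X+1..0
    acc = 0.0
    for j in range(i0 - 1, -1, -1):
        if np.isnan(logr[j + 1]):
            break
        acc += logr[j + 1]
        out[j] = math.exp(acc)
    # X > 0: RNOR(X) = prod_{i=1..X} denom(i)/numer(i) -> inverse ratios at 1..X
    acc = 0.0
    for j in range(i0 + 1, n):
        if np.isnan(logr[j]):
            break
        acc -= logr[j]
        out[j] = math.exp(acc)
    return NormalizedProfile1D(axis=axis, index=index, start=start, values=out)


def lateral_row_profile(
    mc_row: np.ndarray, mlat_row: np.ndarray, x_min: int, row_index: int = 0
) -> NormalizedProfile1D:
    """Relative lateral profile of one grid row from MC and MLAT-1 readings.

    ``mc_row`` and ``mlat_row`` are aligned reading vectors over grid
    indices ``x_min..``; the shifted measurement is the one-step
    left-shifted irradiation, so detector X reads the beam at X-1.
    """
    return _chain(
        np.asarray(mlat_row, dtype=float),
        np.asarray(mc_row, dtype=float),
        x_min,
        "lateral",
        row_index,
    )


def longitudinal_profile(
    mc_col: np.ndarray, mlng_col: np.ndarray, y_min: int, col_index: int = 0
) -> NormalizedProfile1D:
    """Relative longitudinal profile of one grid column, as the lateral case
    with axes swapped."""
    return _chain(
        np.asarray(mlng_col, dtype=float),
        np.asarray(mc_col, dtype=float),
        y_min,
        "longitudinal",
        col_index,
    )


def compose_2d(
    lateral_rows: dict[int, NormalizedProfile1D],
    central_longitudinal: NormalizedProfile1D,
    grid: GridSpec,
) -> NormalizedProfile2D:
    """Reweigh per-row lateral profiles by the central longitudinal profile:
    RNOR(X, Y) = RXNOR(X, Y) * RYNOR(0, Y)."""
    values = np.full((grid.ny, grid.nx), np.nan)
    for y_index, row in lateral_rows.items():
        w = central_longitudinal.value(y_index)
        if math.isnan(w):
            if np.any(np.isfinite(row.values)):
                raise ReconstructionError(
                    f"central longitudinal profile has no value at row {y_index}"
                )
            continue
        j = grid.row_of(y_index)
        for x_index in row.indices:
            v = row.value(x_index)
            if not math.isnan(v):
                values[j, grid.col_of(x_index)] = v * w
    return NormalizedProfile2D(grid=grid, values=values)


@dataclass
class IterativeReconstruction:
    """All 1D chains of a ratio-chain reconstruction plus the composed 2D map.

    ``rxnor_rows`` maps each grid row index Y to its lateral profile;
    ``rynor_cols`` maps each grid column index X to its longitudinal
    profile (only column 0 enters the composition, the rest serve
    error-locking and diagnostics).
    """

    grid: GridSpec
    rxnor_rows: dict[int, NormalizedProfile1D]
    rynor_cols: dict[int, NormalizedProfile1D]

    def compose(self) -> NormalizedProfile2D:
        central = self.rynor_cols.get(0)
        if central is None:
            raise ReconstructionError("central longitudinal column is missing")
        return compose_2d(self.rxnor_rows, central, self.grid)


def reconstruct_2dbp(
    mc, mlat, mlng, geometry: ArrayGeometry, grid: GridSpec
) -> IterativeReconstruction:
    """Ratio-chain reconstruction from the three wide-field measurements.

    ``mc`` is unshifted, ``mlat`` shifted one step laterally left
    (shift_steps (-1, 0)) and ``mlng`` one step longitudinally
    (shift_steps (0, -1)).  Every grid row gets a lateral chain and every
    grid column a longitudinal chain.
    """
    for m, expected, label in (
        (mc, (0, 0), "MC"),
        (mlat, (-1, 0), "MLAT-1"),
        (mlng, (0, -1), "MLNG-1"),
    ):
        got = tuple(np.sign(m.shift_steps))
        if got != expected:
            raise ReconstructionError(
                f"{label} measurement must have shift direction {expected}, got "
                f"{tuple(m.shift_steps)}"
            )
    mc_g = readings_on_grid(mc, geometry, grid)
    mlat_g = readings_on_grid(mlat, geometry, grid)
    mlng_g = readings_on_grid(mlng, geometry, grid)
    rows = {}
    for j, y_index in enumerate(grid.y_indices):
        if np.isfinite(mc_g[j]).any():
            rows[int(y_index)] = lateral_row_profile(
                mc_g[j], mlat_g[j], grid.x_min, int(y_index)
            )
    cols = {}
    for i, x_index in enumerate(grid.x_indices):
        if np.isfinite(mc_g[:, i]).any():
            cols[int(x_index)] = longitudinal_profile(
                mc_g[:, i], mlng_g[:, i], grid.y_min, int(x_index)
            )
    return IterativeReconstruction(grid=grid, rxnor_rows=rows, rynor_cols=cols)


def _scan_positions(scan: dict[int,], label: str) -> tuple[np.ndarray, int]:
    if 0 not in scan:
        raise ReconstructionError(f"{label} scan must include position 0")
    pos = np.array(sorted(scan), dtype=int)
    if pos.size > 1:
        steps = np.diff(pos)
        if not np.all(steps == steps[0]):
            raise ReconstructionError(
                f"{label} scan positions {pos.tolist()} are not a regular sequence"
            )
        return pos, int(steps[0])
    return pos, 1


def reconstruct_greer(
    wide,
    lateral_scan: dict[int,],
    longitudinal_scan: dict[int,],
    geometry: ArrayGeometry,
    grid: GridSpec,
) -> NormalizedProfile2D:
    """Noniterative 2D reconstruction from narrow-field scans.

    ``lateral_scan[p]`` is the narrow-strip irradiation whose center lands
    on array position p (the array shifted by -p steps), so the detectors
    of column p all receive the central strip fluence; their readings
    relative to the p = 0 exposure are the relative sensitivities
    S(p, Y)/S(0, Y).  Dividing the wide-field reading ratios by them gives
    the lateral profile of every row, with each point depending only on its
    own pair of measurements.  The central longitudinal profile is obtained
    the same way from ``longitudinal_scan`` and composes the 2D profile.

    The result lives on a grid at the scan resolution, which may be coarser
    than the detector grid.
    """
    lat_pos, lat_step = _scan_positions(lateral_scan, "lateral")
    lng_pos, lng_step = _scan_positions(longitudinal_scan, "longitudinal")
    mc_g = readings_on_grid(wide, geometry, grid)

    def _ratio(a: float, b: float, what: str) -> float:
        if np.isnan(a) or np.isnan(b):
            return math.nan
        if a <= 0 or b <= 0:
            raise ReconstructionError(f"non-positive reading in {what}")
        return a / b

    # lateral relative sensitivities and per-row profiles
    lat_grids = {p: readings_on_grid(m, geometry, grid) for p, m in lateral_scan.items()}
    lng_grids = {q: readings_on_grid(m, geometry, grid) for q, m in longitudinal_scan.items()}
    out_grid = GridSpec(
        step_x_cm=grid.step_x_cm * lat_step,
        step_y_cm=grid.step_y_cm * lng_step,
        x_min=int(lat_pos[0]) // lat_step,
        x_max=int(lat_pos[-1]) // lat_step,
        y_min=int(lng_pos[0]) // lng_step,
        y_max=int(lng_pos[-1]) // lng_step,
    )
    values = np.full((out_grid.ny, out_grid.nx), np.nan)
    i0 = grid.col_of(0)
    for q in lng_pos:
        j = grid.row_of(int(q))
        rel_s_lng = _ratio(
            lng_grids[int(q)][j, i0],
            lng_grids[0][grid.row_of(0), i0],
            f"longitudinal scan at {q}",
        )
        rynor0 = _ratio(mc_g[j, i0], mc_g[grid.row_of(0), i0], "wide field")
        rynor0 = rynor0 / rel_s_lng
        if math.isnan(rynor0):
            continue
        for p in lat_pos:
            i = grid.col_of(int(p))
            rel_s_lat = _ratio(
                lat_grids[int(p)][j, i],
                lat_grids[0][j, i0],
                f"lateral scan at {p}",
            )
            rxnor = _ratio(mc_g[j, i], mc_g[j, i0], "wide field") / rel_s_lat
            values[
                out_grid.row_of(int(q) // lng_step), out_grid.col_of(int(p) // lat_step)
            ] = rxnor * rynor0
    # exact unity at the origin by construction, up to the final products
    values[out_grid.row_of(0), out_grid.col_of(0)] = 1.0
    return NormalizedProfile2D(grid=out_grid, values=values)
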