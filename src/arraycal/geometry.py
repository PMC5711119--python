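"""Detector-array layouts and grid/physical coordinate conventions.

Coordinates are CAX-centered, in cm, in the detector plane at 100 cm
source-to-detector distance.  +x is lateral (crossplane), +y is
longitudinal (inplane, toward the gantry).  Reconstruction-grid indices
(X, Y) are signed integers with (0, 0) on the CAX; one unit of X or Y is
the array-shifting step, an integer multiple of the detector spacing.

A "shift left by one step" places the detector with grid index X over
beam position X - 1: shifting the array by s cm moves a detector whose
unshifted position is x to beam coordinate x + s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np


class GeometryError(ValueError):
    """Invalid array-layout or grid parameters."""


_POS_TOL = 1e-9  # cm; positions are exact multiples of spacings in practice


@dataclass(frozen=True)
class GridSpec:
    """Integer reconstruction grid: step sizes (cm) and signed index ranges.

    One grid unit corresponds to the array shifting distance; ranges are
    inclusive and must contain 0.
    """

    step_x_cm: float
    step_y_cm: float
    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if self.step_x_cm <= 0 or self.step_y_cm <= 0:
            raise GeometryError("grid steps must be positive")
        if not (self.x_min <= 0 <= self.x_max and self.y_min <= 0 <= self.y_max):
            raise GeometryError("grid index ranges must include 0")

    @property
    def nx(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def ny(self) -> int:
        return self.y_max - self.y_min + 1

    @property
    def x_indices(self) -> np.ndarray:
        return np.arange(self.x_min, self.x_max + 1)

    @property
    def y_indices(self) -> np.ndarray:
        return np.arange(self.y_min, self.y_max + 1)

    def col_of(self, x_index: int) -> int:
        return int(x_index) - self.x_min

    def row_of(self, y_index: int) -> int:
        return int(y_index) - self.y_min


@dataclass(frozen=True)
class ArrayGeometry:
    """A rectangular (possibly staggered, possibly masked) detector layout.

    ``mask`` is True where a physical detector exists.  ``row_stagger_cm``
    is the lateral offset applied to odd-index rows.  Detector identity is
    the (row, col) index; physical position is derived.
    """

    name: str
    n_rows: int
    n_cols: int
    col_spacing_cm: float
    row_spacing_cm: float
    row_stagger_cm: float
    mask: np.ndarray = field(repr=False)
    origin_index: tuple[int, int]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise GeometryError(
                f"mask shape {mask.shape} != ({self.n_rows}, {self.n_cols})"
            )
        object.__setattr__(self, "mask", mask)
        r0, c0 = self.origin_index
        if not (0 <= r0 < self.n_rows and 0 <= c0 < self.n_cols):
            raise GeometryError("origin_index outside the array")
        if not mask[r0, c0]:
            raise GeometryError("origin detector must be unmasked")
        if self.row_stagger_cm != 0.0 and r0 % 2 == 1:
            raise GeometryError(
                "origin detector must sit on an unstaggered (even) row"
            )
        if self.col_spacing_cm <= 0 or self.row_spacing_cm <= 0:
            raise GeometryError("detector spacings must be positive")

    # -- physical coordinates -------------------------------------------------

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Unshifted physical (x, y) of every (row, col), masked or not."""
        r0, c0 = self.origin_index
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        x = (cols[None, :] - c0) * self.col_spacing_cm + self.row_stagger_cm * (
            rows[:, None] % 2
        )
        y = (rows[:, None] - r0) * self.row_spacing_cm * np.ones_like(
            cols[None, :], dtype=float
        )
        return x, y

    @property
    def n_detectors(self) -> int:
        return int(self.mask.sum())

    def validate_grid(self, grid: GridSpec) -> None:
        """Grid steps must be integer multiples of the detector spacings."""
        for step, spacing, label in (
            (grid.step_x_cm, self.col_spacing_cm, "x"),
            (grid.step_y_cm, self.row_spacing_cm, "y"),
        ):
            ratio = step / spacing
            if abs(ratio - round(ratio)) > _POS_TOL or round(ratio) < 1:
                raise GeometryError(
                    f"grid step_{label} {step} cm is not an integer multiple "
                    f"of the {spacing} cm detector spacing"
                )

    def grid_detector_map(self, grid: GridSpec) -> np.ndarray:
        """(ny, nx, 2) array of (row, col) of the detector at each grid node.

        Entries are -1 where no unmasked detector coincides with the node.
        The nodes with a detector form the reconstruction-grid subset.
        """
        self.validate_grid(grid)
        x, y = self.positions()
        lookup: dict[tuple[int, int], tuple[int, int]] = {}
        scale = 1.0 / _POS_TOL
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                if self.mask[r, c]:
                    key = (round(x[r, c] * scale), round(y[r, c] * scale))
                    lookup[key] = (r, c)
        out = np.full((grid.ny, grid.nx, 2), -1, dtype=int)
        for j, yi in enumerate(grid.y_indices):
            for i, xi in enumerate(grid.x_indices):
                key = (
                    round(xi * grid.step_x_cm * scale),
                    round(yi * grid.step_y_cm * scale),
                )
                if key in lookup:
                    out[j, i] = lookup[key]
        return out

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        """Self-describing document (mask stored as per-row run lengths)."""
        rle = []
        for r in range(self.n_rows):
            row = self.mask[r]
            runs, val, count = [], bool(row[0]), 0
            for v in row:
                if bool(v) == val:
                    count += 1
                else:
                    runs.append(count)
                    val, count = bool(v), 1
            runs.append(count)
            rle.append({"first": bool(row[0]), "runs": runs})
        return {
            "name": self.name,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "col_spacing_cm": self.col_spacing_cm,
            "row_spacing_cm": self.row_spacing_cm,
            "row_stagger_cm": self.row_stagger_cm,
            "origin_index": list(self.origin_index),
            "mask_rle": rle,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ArrayGeometry":
        mask = np.zeros((doc["n_rows"], doc["n_cols"]), dtype=bool)
        for r, spec in enumerate(doc["mask_rle"]):
            val, c = bool(spec["first"]), 0
            for run in spec["runs"]:
                mask[r, c : c + run] = val
                val, c = not val, c + run
        return cls(
            name=doc["name"],
            n_rows=doc["n_rows"],
            n_cols=doc["n_cols"],
            col_spacing_cm=doc["col_spacing_cm"],
            row_spacing_cm=doc["row_spacing_cm"],
            row_stagger_cm=doc["row_stagger_cm"],
            mask=mask,
            origin_index=tuple(doc["origin_index"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ArrayGeometry":
        return cls.from_dict(json.loads(text))


# -- constructors -------------------------------------------------------------


def build_grid_geometry(
    n_rows: int, n_cols: int, spacing_cm: float
) -> ArrayGeometry:
    """Regular odd-sized rectangular layout with its center detector on the CAX."""
    if n_rows < 3 or n_cols < 3 or n_rows % 2 == 0 or n_cols % 2 == 0:
        raise GeometryError(
            f"n_rows and n_cols must be odd and >= 3 so a central detector "
            f"exists; got ({n_rows}, {n_cols})"
        )
    if spacing_cm <= 0:
        raise GeometryError(f"spacing must be positive; got {spacing_cm}")
    return ArrayGeometry(
        name=f"grid:{n_rows}x{n_cols}:{spacing_cm:g}",
        n_rows=n_rows,
        n_cols=n_cols,
        col_spacing_cm=spacing_cm,
        row_spacing_cm=spacing_cm,
        row_stagger_cm=0.0,
        mask=np.ones((n_rows, n_cols), dtype=bool),
        origin_index=(n_rows // 2, n_cols // 2),
    )


def build_mapcheck2_geometry(origin_index: tuple[int, int] | None = None) -> ArrayGeometry:
    """The MapCHECK2 diode layout.

    65 rows at 0.5 cm longitudinal pitch (y = -16..16 cm), 1 cm lateral
    detector spacing within each row, odd rows staggered 0.5 cm laterally,
    and no detectors in the four 7x7 cm^2 corner triangles.  Even rows carry
    detectors at integer (x, y) positions: these form the 1 cm
    reconstruction grid (about half of the 1527 detectors).  The overall
    active area is 26 cm laterally by 32 cm longitudinally.
    """
    n_rows, n_cols = 65, 27
    origin = (32, 13) if origin_index is None else tuple(origin_index)
    mask = np.ones((n_rows, n_cols), dtype=bool)
    # odd rows are offset +0.5 cm, so their last column would sit at
    # x = +13.5 cm, outside the 26 cm lateral extent
    mask[1::2, -1] = False
    geom = ArrayGeometry(
        name="mapcheck2",
        n_rows=n_rows,
        n_cols=n_cols,
        col_spacing_cm=1.0,
        row_spacing_cm=0.5,
        row_stagger_cm=0.5,
        mask=mask,
        origin_index=origin,
    )
    x, y = geom.positions()
    # four 7x7 corner triangles of the 26x32 bounding box; detectors on the
    # hypotenuse are physical and kept
    corner = (np.abs(x) + np.abs(y)) > (6.0 + 9.0 + 7.0) + _POS_TOL
    mask = mask & ~corner
    return ArrayGeometry(
        name="mapcheck2",
        n_rows=n_rows,
        n_cols=n_cols,
        col_spacing_cm=1.0,
        row_spacing_cm=0.5,
        row_stagger_cm=0.5,
        mask=mask,
        origin_index=origin,
    )


def mapcheck2_default_grid() -> GridSpec:
    """1 cm reconstruction grid covering the MapCHECK2 active area."""
    return GridSpec(
        step_x_cm=1.0, step_y_cm=1.0, x_min=-13, x_max=13, y_min=-16, y_max=16
    )


def detector_positions(
    geometry: ArrayGeometry, shift_x_cm: float = 0.0, shift_y_cm: float = 0.0
) -> list[tuple[tuple[int, int], float, float]]:
    """Beam-frame positions of unmasked detectors for a translated array.

    Returns [(detector_id, x, y), ...] with x, y relative to the beam CAX:
    a detector at unshifted position (x, y) samples beam coordinate
    (x + shift_x, y + shift_y).
    """
    x, y = geometry.positions()
    out = []
    for r, c in zip(*np.nonzero(geometry.mask)):
        out.append(
            ((int(r), int(c)), float(x[r, c] + shift_x_cm), float(y[r, c] + shift_y_cm))
        )
    return out
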