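"""Per-detector sensitivities from a reconstructed beam profile.

The reconstructed profile lives on a regular grid; physical detectors of
a staggered array do not all coincide with grid nodes, so the profile is
bilinearly interpolated to detector positions (bilinear is monotone and
cannot overshoot on bowl-shaped profiles; bicubic is available behind a
flag).  The sensitivity of detector (x, y) is then

    s(x, y) = mc_nor(x, y) / rnor(x, y)

where mc_nor is the unshifted wide-field measurement normalized to the
central detector and rnor the interpolated normalized profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import ArrayGeometry

__all__ = [
    "CalibrationError",
    "SensitivityMap",
    "DeviationStats",
    "interpolate_to_detectors",
    "compute_sensitivities",
    "apply_calibration",
    "profile_deviation_stats",
    "CalibrationResult",
    "calibrate_session",
]


class CalibrationError(ValueError):
    """Unusable calibration inputs."""


@dataclass
class SensitivityMap:
    """Per-detector multiplicative sensitivities, unity at the
    normalization detector; NaN where masked or not calibratable."""

    values: np.ndarray
    normalization_index: tuple[int, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r0, c0 = self.normalization_index
        v0 = self.values[r0, c0]
        if not (math.isfinite(v0) and v0 > 0):
            raise CalibrationError(
                "sensitivity at the normalization detector must be positive"
            )
        if np.any(self.values[np.isfinite(self.values)] <= 0):
            raise CalibrationError("sensitivities must be positive where defined")


def interpolate_to_detectors(
    profile, geometry: ArrayGeometry, method: str = "linear"
) -> tuple[np.ndarray, list[tuple[tuple[int, int], str]]]:
    """Interpolate a gridded 2D profile to physical detector positions.

    Returns the per-detector profile (NaN where unavailable) and an
    exclusion report listing detectors outside the grid's hull or adjacent
    to undefined grid nodes -- these are never extrapolated.  ``method``
    may be "linear" (default, exact at grid nodes and for bilinear
    functions) or "cubic".
    """
    if method not in ("linear", "cubic"):
        raise CalibrationError(f"unknown interpolation method {method!r}")
    grid = profile.grid
    xs = grid.x_indices * grid.step_x_cm
    ys = grid.y_indices * grid.step_y_cm
    interp = RegularGridInterpolator(
        (ys, xs), profile.values, method=method, bounds_error=False, fill_value=np.nan
    )
    x, y = geometry.positions()
    pts = np.column_stack([y[geometry.mask], x[geometry.mask]])
    vals = interp(pts)
    # exact at grid nodes regardless of neighbouring NaNs
    on_x = np.isclose(pts[:, 1] / grid.step_x_cm, np.round(pts[:, 1] / grid.step_x_cm))
    on_y = np.isclose(pts[:, 0] / grid.step_y_cm, np.round(pts[:, 0] / grid.step_y_cm))
    node = on_x & on_y
    if node.any():
        ix = np.round(pts[node, 1] / grid.step_x_cm).astype(int)
        iy = np.round(pts[node, 0] / grid.step_y_cm).astype(int)
        inside = (
            (ix >= grid.x_min) & (ix <= grid.x_max)
            & (iy >= grid.y_min) & (iy <= grid.y_max)
        )
        direct = np.full(ix.size, np.nan)
        direct[inside] = profile.values[iy[inside] - grid.y_min, ix[inside] - grid.x_min]
        vals[node] = direct
    out = np.full((geometry.n_rows, geometry.n_cols), np.nan)
    out[geometry.mask] = vals
    exclusions = []
    rows, cols = np.nonzero(geometry.mask)
    for (r, c), v, p in zip(zip(rows, cols), vals, pts):
        if not math.isfinite(v):
            inside = (
                grid.x_min * grid.step_x_cm <= p[1] <= grid.x_max * grid.step_x_cm
                and grid.y_min * grid.step_y_cm <= p[0] <= grid.y_max * grid.step_y_cm
            )
            reason = "adjacent grid node undefined" if inside else "outside grid hull"
            exclusions.append(((int(r), int(c)), reason))
    return out, exclusions


def compute_sensitivities(
    mc_nor: np.ndarray,
    rnor: np.ndarray,
    geometry: ArrayGeometry,
    provenance: str = "",
) -> SensitivityMap:
    """Elementwise s = mc_nor / rnor, renormalized to exactly 1 at the
    geometry origin detector."""
    mc_nor = np.asarray(mc_nor, dtype=float)
    rnor = np.asarray(rnor, dtype=float)
    if mc_nor.shape != rnor.shape or mc_nor.shape != geometry.mask.shape:
        raise CalibrationError("mc_nor/rnor shapes do not match the geometry")
    if np.any(rnor[np.isfinite(rnor)] <= 0):
        raise CalibrationError("rnor must be positive at all calibratable detectors")
    r0, c0 = geometry.origin_index
    with np.errstate(invalid="ignore", divide="ignore"):
        s = mc_nor / rnor
    s = np.where(geometry.mask, s, np.nan)
    s0 = s[r0, c0]
    if not (math.isfinite(s0) and s0 > 0):
        raise CalibrationError("normalization detector has no usable sensitivity")
    return SensitivityMap(
        values=s / s0, normalization_index=(r0, c0), provenance=provenance
    )


def apply_calibration(measurement, smap: SensitivityMap) -> np.ndarray:
    """Sensitivity-corrected readings: reading / s per detector."""
    readings = np.asarray(measurement.readings, dtype=float)
    if readings.shape != smap.values.shape:
        raise CalibrationError(
            f"readings shape {readings.shape} != sensitivity shape {smap.values.shape}"
        )
    with np.errstate(invalid="ignore"):
        return readings / smap.values


@dataclass
class DeviationStats:
    """Summary of per-detector absolute percent differences |a-b|/b*100."""

    mean_abs_pct: float
    sd_abs_pct: float
    max_abs_pct: float
    n: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mean_abs_pct": self.mean_abs_pct,
            "sd_abs_pct": self.sd_abs_pct,
            "max_abs_pct": self.max_abs_pct,
            "n": self.n,
            "hist_counts": self.hist_counts.tolist(),
            "hist_edges": self.hist_edges.tolist(),
        }


def profile_deviation_stats(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | None = None,
    bin_width_pct: float = 0.1,
) -> DeviationStats:
    """Mean/SD/max of |a - b|/b in percent over the common support, with a
    binned histogram; ``b`` is the reference (denominator)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    common = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        common &= np.asarray(mask, dtype=bool)
    if not common.any():
        raise CalibrationError("no common unmasked support")
    dev = np.abs(a[common] - b[common]) / b[common] * 100.0
    top = max(float(dev.max()), bin_width_pct)
    edges = np.arange(0.0, top + bin_width_pct, bin_width_pct)
    counts, edges = np.histogram(dev, bins=edges)
    return DeviationStats(
        mean_abs_pct=float(dev.mean()),
        sd_abs_pct=float(dev.std(ddof=1)) if dev.size > 1 else 0.0,
        max_abs_pct=float(dev.max()),
        n=int(dev.size),
        hist_counts=counts,
        hist_edges=edges,
    )


# -- end-to-end session driver ------------------------------------------------

METHODS = ("2dbp", "2dbp_unlocked", "greer")


@dataclass
class CalibrationResult:
    """Everything one calibration run produces."""

    method: str
    sensitivities: SensitivityMap
    profile: object  # NormalizedProfile2D
    error_estimates: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)

    def report(self) -> dict:
        rep = {
            "method": self.method,
            "n_calibrated": int(np.isfinite(self.sensitivities.values).sum()),
            "n_excluded": len(self.exclusions),
            "error_estimates": {
                axis: {
                    "e1_pct": est.e1_pct,
                    "e2_pct": est.e2_pct,
                    "n_rows": est.diagnostics.get("n_rows"),
                    "e1_sd_pct": 100.0 * est.diagnostics.get("e1_sd", 0.0),
                    "e2_sd_pct": 100.0 * est.diagnostics.get("e2_sd", 0.0),
                }
                for axis, est in self.error_estimates.items()
            },
        }
        return rep


def calibrate_session(session, method: str = "2dbp") -> CalibrationResult:
    """Run one calibration method end-to-end on a measurement session.

    ``session`` provides geometry, grid, config and labelled measurements
    (as produced by the simulator or read from disk).  Methods: the
    iterative reconstruction with ("2dbp") or without ("2dbp_unlocked")
    error-locking, or the noniterative narrow-field-scan reference
    ("greer").
    """
    from .errorlock import (
        LockingTriad,
        anchor_points,
        correct_profile,
        estimate_axis_errors,
        triad_relative_sensitivities,
    )
    from .reconstruction import reconstruct_2dbp, reconstruct_greer

    if method not in METHODS:
        raise CalibrationError(f"unknown method {method!r}; expected one of {METHODS}")
    geom, grid = session.geometry, session.grid
    mc = session.by_role("mc")
    estimates: dict = {}
    if method == "greer":
        lat, lng = session.scan("lat"), session.scan("lng")
        if not lat or not lng:
            raise CalibrationError(
                "greer calibration requires lateral and longitudinal narrow-field scans"
            )
        profile = reconstruct_greer(mc, lat, lng, geom, grid)
    else:
        rec = reconstruct_2dbp(
            mc, session.by_role("mlat"), session.by_role("mlng"), geom, grid
        )
        if method == "2dbp":
            cfg = session.config
            lock = {
                "lateral": (cfg.anchors_lat, "lock_lat", rec.rxnor_rows),
                "longitudinal": (cfg.anchors_lng, "lock_lng", rec.rynor_cols),
            }
            for axis, ((pa, pc), prefix, rows) in lock.items():
                triad = LockingTriad(
                    a=session.by_role(f"{prefix}_a"),
                    b=session.by_role(f"{prefix}_b"),
                    c=session.by_role(f"{prefix}_c"),
                    position_a=pa,
                    position_c=pc,
                    axis=axis,
                )
                rel = triad_relative_sensitivities(triad, geom, grid)
                anchors = anchor_points(mc, rel, triad, geom, grid)
                est = estimate_axis_errors(rows, anchors, grid, triad)
                estimates[axis] = est
                for key in rows:
                    rows[key] = correct_profile(rows[key], est)
        profile = rec.compose()
    rnor_det, exclusions = interpolate_to_detectors(profile, geom)
    r0, c0 = geom.origin_index
    mc0 = mc.readings[r0, c0]
    if not (math.isfinite(mc0) and mc0 > 0):
        raise CalibrationError("central detector reading is unusable")
    mc_nor = mc.readings / mc0
    smap = compute_sensitivities(
        mc_nor, rnor_det, geom, provenance=f"method={method} plan={session.config.plan}"
    )
    return CalibrationResult(
        method=method,
        sensitivities=smap,
        profile=profile,
        error_estimates=estimates,
        exclusions=exclusions,
    )
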