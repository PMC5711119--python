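"""Synthetic calibration sessions with known ground truth.

Emulates what a linac + 2D array measurement session produces: a smooth
2D beam fluence (bowl-shaped for flattened beams, peaked for FFF),
per-detector multiplicative sensitivities, inter-measurement output
variation, array positioning error, and multiplicative per-detector
noise.  The forward model for one detector is

    reading = MU * output_scale * noise * R(x + shift + pos_err) * S(detector)

so noiseless, perturbation-free sessions satisfy the shifted-measurement
identities MC(X,Y) = R(X,Y)*S(X,Y), MLAT-1(X,Y) = R(X-1,Y)*S(X,Y) and
MLNG-1(X,Y) = R(X,Y-1)*S(X,Y) to machine precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .geometry import ArrayGeometry, GridSpec
from .calibration import SensitivityMap

__all__ = [
    "ProfileModel",
    "FieldSpec",
    "PerturbationSpec",
    "Measurement",
    "SessionConfig",
    "SimulatedSession",
    "evaluate_profile",
    "sample_sensitivities",
    "simulate_measurement",
    "generate_session",
]

# default bowl: relative profile reaches exactly 1.08 at r = 15 cm
BOWL_RISE_DEFAULT = 0.08
BOWL_REF_CM_DEFAULT = 15.0
# apex-rounding radius: with 1.08 at 15 cm this gives a relative gradient of
# ~0.0059/cm away from the core, i.e. ~0.29% per 0.5 cm — the perturbation
# scale large-field array measurements show for sub-spacing displacements
BOWL_CORE_CM_DEFAULT = 1.5

# conversion between the 80-20 penumbra width and the Gaussian edge sigma:
# the erf edge passes 0.2/0.8 at z = +-0.8416 sigma
_P8020_TO_SIGMA = 1.0 / (2.0 * 0.8416212335729143)


class SimulationError(ValueError):
    """Inconsistent simulation parameters."""


@dataclass(frozen=True)
class FieldSpec:
    """Rectangular open-field dimensions at the detector plane."""

    width_cm: float   # lateral (x) extent
    height_cm: float  # longitudinal (y) extent
    label: str = ""

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise SimulationError("field dimensions must be positive")


@dataclass(frozen=True)
class ProfileModel:
    """Sensitivity-free 2D beam fluence, evaluable at any (x, y) in cm.

    kinds:
      * ``flat``     -- constant inside the field aperture;
      * ``bowl``     -- the shape of flattened linac beams: a smoothed cone
                        1 + s*(sqrt(r^2 + core^2) - core), flat-ish within
                        the central ``bowl_core_cm`` and rising
                        quasi-linearly in r beyond it, with the slope s
                        fixed so the relative profile is exactly
                        1 + ``bowl_rise`` at ``bowl_ref_cm`` from the CAX
                        (default 1.08 at 15 cm).  The quasi-linear rise
                        matches what large-field array measurements show:
                        a displacement by d cm perturbs a reading by about
                        the same relative amount s*d anywhere away from the
                        center.  Optional even-polynomial terms a2*r^2 +
                        a4*r^4 and a linear tilt model curvature and beam
                        asymmetry;
      * ``fff_peak`` -- Gaussian-peaked, as for flattening-filter-free beams;
      * ``custom``   -- arbitrary callable f(x, y) of in-field fluence.

    The aperture is a ``field`` window with error-function edges of 80-20
    penumbra width ``penumbra_cm``; ``narrow_flat`` replaces the in-field
    shape with a constant (used to stress the equal-fluence assumption of
    narrow-field measurements).
    """

    kind: str = "bowl"
    bowl_rise: float = BOWL_RISE_DEFAULT
    bowl_ref_cm: float = BOWL_REF_CM_DEFAULT
    bowl_core_cm: float = BOWL_CORE_CM_DEFAULT
    a2: float = 0.0
    a4: float = 0.0
    tilt_x: float = 0.0  # per cm, models beam asymmetry
    tilt_y: float = 0.0
    fff_sigma_cm: float = 20.0
    custom: object = None
    penumbra_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "bowl", "fff_peak", "custom"):
            raise SimulationError(f"unknown profile kind {self.kind!r}")
        if self.kind == "custom" and not callable(self.custom):
            raise SimulationError("custom profile requires a callable")
        if self.bowl_core_cm < 0 or self.bowl_ref_cm <= 0:
            raise SimulationError("bowl_core_cm must be >= 0 and bowl_ref_cm > 0")
        if self.penumbra_cm <= 0:
            raise SimulationError("penumbra width must be positive")

    def infield(self, x_cm, y_cm) -> np.ndarray:
        """Open-beam fluence shape without the aperture window."""
        x = np.asarray(x_cm, dtype=float)
        y = np.asarray(y_cm, dtype=float)
        if self.kind == "flat":
            return np.ones(np.broadcast(x, y).shape)
        if self.kind == "custom":
            return np.asarray(self.custom(x, y), dtype=float)
        r2 = x * x + y * y
        if self.kind == "fff_peak":
            base = np.exp(-r2 / (2.0 * self.fff_sigma_cm**2))
        else:
            base = 1.0 + self.a2 * r2 + self.a4 * r2 * r2
            if self.bowl_rise != 0.0:
                w = self.bowl_core_cm
                slope = self.bowl_rise / (
                    math.hypot(self.bowl_ref_cm, w) - w
                )
                base = base + slope * (np.sqrt(r2 + w * w) - w)
        return base * (1.0 + self.tilt_x * x + self.tilt_y * y)

    def window(self, field: FieldSpec, x_cm, y_cm) -> np.ndarray:
        """Aperture transmission with erf penumbra, ~1 in-field, ~0 outside."""
        s = self.penumbra_cm * _P8020_TO_SIGMA * math.sqrt(2.0)
        x = np.asarray(x_cm, dtype=float)
        y = np.asarray(y_cm, dtype=float)
        tx = 0.5 * (erf((field.width_cm / 2 - x) / s) + erf((field.width_cm / 2 + x) / s))
        ty = 0.5 * (erf((field.height_cm / 2 - y) / s) + erf((field.height_cm / 2 + y) / s))
        return tx * ty


def evaluate_profile(
    model: ProfileModel,
    x_cm,
    y_cm,
    field: FieldSpec | None = None,
    narrow_flat: bool = False,
) -> np.ndarray:
    """Fluence at (x, y); windowed by the field aperture when given."""
    shape = np.ones(np.broadcast(np.asarray(x_cm), np.asarray(y_cm)).shape)
    if not narrow_flat:
        shape = model.infield(x_cm, y_cm)
    if field is not None:
        shape = shape * model.window(field, x_cm, y_cm)
    return shape


@dataclass(frozen=True)
class PerturbationSpec:
    """Multiplicative perturbations of one irradiation.

    ``output_scale`` models machine output variation (the physical cause of
    the E1 error); ``position_error_cm`` an unintended extra array
    translation (the cause of E2); ``noise_sd_rel`` the relative SD of
    independent multiplicative per-detector noise (truncated at +-5 sigma).
    """

    output_scale: float = 1.0
    position_error_cm: tuple[float, float] = (0.0, 0.0)
    noise_sd_rel: float = 0.0

    def __post_init__(self) -> None:
        if self.output_scale <= 0:
            raise SimulationError("output_scale must be positive")
        if self.noise_sd_rel < 0:
            raise SimulationError("noise_sd_rel must be >= 0")


NEUTRAL = PerturbationSpec()


@dataclass
class Measurement:
    """One irradiation: per-detector readings plus its acquisition context.

    ``readings`` has the geometry's (n_rows, n_cols) shape with NaN at
    masked detectors.  ``shift_steps`` is the intended array translation in
    integer grid steps (positioning error is never part of it).
    """

    readings: np.ndarray
    shift_steps: tuple[int, int]
    field: FieldSpec
    mu: float = 200.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.readings = np.asarray(self.readings, dtype=float)
        if np.any(self.readings[np.isfinite(self.readings)] < 0):
            raise SimulationError("readings must be non-negative")

    @property
    def role(self) -> str:
        return self.meta.get("role", "")


def sample_sensitivities(
    geometry: ArrayGeometry, spread_rel: float, seed
) -> SensitivityMap:
    """Random per-detector sensitivities: 1 + spread * z, z ~ N(0,1) clipped at +-5.

    ``spread_rel = 0`` gives exact unity everywhere; the map is
    reproducible under the seed and NaN at masked detectors.
    """
    if spread_rel < 0:
        raise SimulationError("spread_rel must be >= 0")
    if spread_rel >= 0.2:
        raise SimulationError("spread_rel >= 0.2 would allow non-positive factors")
    rng = np.random.default_rng(seed)
    z = np.clip(rng.standard_normal((geometry.n_rows, geometry.n_cols)), -5.0, 5.0)
    values = 1.0 + spread_rel * z
    values[~geometry.mask] = np.nan
    return SensitivityMap(
        values=values,
        normalization_index=geometry.origin_index,
        provenance="simulated",
    )


def _penumbra_margin(field: FieldSpec, model: ProfileModel, x, y) -> float:
    half_w, half_h = field.width_cm / 2, field.height_cm / 2
    return min(
        float(np.min(half_w - np.abs(x))), float(np.min(half_h - np.abs(y)))
    ) - 2.0 * model.penumbra_cm


def simulate_measurement(
    model: ProfileModel,
    sensitivities: SensitivityMap,
    geometry: ArrayGeometry,
    shift_steps: tuple[int, int],
    grid: GridSpec,
    field: FieldSpec,
    mu: float = 200.0,
    perturb: PerturbationSpec = NEUTRAL,
    rng: np.random.Generator | None = None,
    narrow_flat: bool = False,
    expect_wide: bool = False,
    meta: dict | None = None,
) -> Measurement:
    """Forward-model one irradiation of the (possibly shifted) array."""
    if sensitivities.values.shape != (geometry.n_rows, geometry.n_cols):
        raise SimulationError(
            f"sensitivity shape {sensitivities.values.shape} does not match "
            f"geometry ({geometry.n_rows}, {geometry.n_cols})"
        )
    geometry.validate_grid(grid)
    shift_x = shift_steps[0] * grid.step_x_cm + perturb.position_error_cm[0]
    shift_y = shift_steps[1] * grid.step_y_cm + perturb.position_error_cm[1]
    x, y = geometry.positions()
    bx, by = x + shift_x, y + shift_y  # beam-frame sampling positions
    if expect_wide and _penumbra_margin(field, model, bx[geometry.mask], by[geometry.mask]) < 0:
        warnings.warn(
            "wide-field irradiation places detectors inside the penumbra; "
            "ratio-chain reconstruction assumes penumbra-free readings",
            stacklevel=2,
        )
    fluence = evaluate_profile(model, bx, by, field=field, narrow_flat=narrow_flat)
    readings = mu * perturb.output_scale * fluence * sensitivities.values
    if perturb.noise_sd_rel > 0:
        if rng is None:
            raise SimulationError("noise requested but no rng supplied")
        z = np.clip(rng.standard_normal(readings.shape), -5.0, 5.0)
        readings = readings * (1.0 + perturb.noise_sd_rel * z)
    readings = np.where(geometry.mask, readings, np.nan)
    return Measurement(
        readings=readings,
        shift_steps=tuple(int(s) for s in shift_steps),
        field=field,
        mu=mu,
        meta=dict(meta or {}),
    )


# -- session plans -------------------------------------------------------------

PLANS = ("2dbp_locked", "2dbp_unlocked", "greer")


@dataclass(frozen=True)
class SessionConfig:
    """Measurement-plan parameters (lengths in cm, positions in grid steps).

    Defaults follow the published MapCHECK2 protocol: a 37x37 wide field;
    4 cm-wide lateral / 4 cm-tall longitudinal narrow strips; error-locking
    triads at -11/0/+11 laterally and -14/0/+14 longitudinally; Greer scan
    ranges -12..12 laterally and -16..16 longitudinally.
    """

    plan: str = "2dbp_locked"
    wide_field: FieldSpec = FieldSpec(37.0, 37.0, "wide 37x37")
    narrow_lat_field: FieldSpec = FieldSpec(4.0, 37.0, "narrow 4x37")
    narrow_lng_field: FieldSpec = FieldSpec(37.0, 4.0, "narrow 37x4")
    shift_step: int = 1
    anchors_lat: tuple[int, int] = (-11, 11)
    anchors_lng: tuple[int, int] = (-14, 14)
    scan_lat_range: tuple[int, int] = (-12, 12)
    scan_lng_range: tuple[int, int] = (-16, 16)
    scan_step: int = 1
    mu: float = 200.0
    noise_sd_rel: float = 0.0
    narrow_flat: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plan not in PLANS:
            raise SimulationError(f"unknown plan {self.plan!r}; expected one of {PLANS}")
        a, c = self.anchors_lat
        if not (a < 0 < c):
            raise SimulationError("lateral anchors must satisfy A < 0 < C")
        a, c = self.anchors_lng
        if not (a < 0 < c):
            raise SimulationError("longitudinal anchors must satisfy A < 0 < C")
        if self.shift_step < 1 or self.scan_step < 1:
            raise SimulationError("shift_step and scan_step must be >= 1")
        for lo, hi in (self.scan_lat_range, self.scan_lng_range):
            if not (lo <= 0 <= hi):
                raise SimulationError("scan ranges must include 0")

    def plan_shifts(self) -> list[tuple[str, tuple[int, int], FieldSpec]]:
        """Ordered (role, shift_steps, field) tuples of the plan.

        A narrow field "irradiated at array position p" is realized by
        shifting the array by -p steps, which places the detectors at p
        under the beam center.
        """
        s = self.shift_step
        wide = [
            ("mc", (0, 0), self.wide_field),
            ("mlat", (-s, 0), self.wide_field),
            ("mlng", (0, -s), self.wide_field),
        ]
        if self.plan == "2dbp_unlocked":
            return wide
        if self.plan == "2dbp_locked":
            (a_lat, c_lat), (a_lng, c_lng) = self.anchors_lat, self.anchors_lng
            return wide + [
                ("lock_lat_a", (-a_lat, 0), self.narrow_lat_field),
                ("lock_lat_b", (0, 0), self.narrow_lat_field),
                ("lock_lat_c", (-c_lat, 0), self.narrow_lat_field),
                ("lock_lng_a", (0, -a_lng), self.narrow_lng_field),
                ("lock_lng_b", (0, 0), self.narrow_lng_field),
                ("lock_lng_c", (0, -c_lng), self.narrow_lng_field),
            ]
        out = [("mc", (0, 0), self.wide_field)]
        lo, hi = self.scan_lat_range
        for p in range(lo, hi + 1, self.scan_step):
            out.append((f"scan_lat:{p}", (-p, 0), self.narrow_lat_field))
        lo, hi = self.scan_lng_range
        for p in range(lo, hi + 1, self.scan_step):
            out.append((f"scan_lng:{p}", (0, -p), self.narrow_lng_field))
        return out


@dataclass
class SimulatedSession:
    """A labelled measurement set plus the ground truth that produced it."""

    config: SessionConfig
    geometry: ArrayGeometry
    grid: GridSpec
    measurements: list[Measurement]
    model: ProfileModel
    sensitivities: SensitivityMap

    def by_role(self, role: str) -> Measurement:
        found = [m for m in self.measurements if m.role == role]
        if len(found) != 1:
            raise SimulationError(
                f"session has {len(found)} measurements with role {role!r}"
            )
        return found[0]

    def scan(self, axis: str) -> dict[int, Measurement]:
        prefix = f"scan_{axis}:"
        return {
            int(m.role[len(prefix):]): m
            for m in self.measurements
            if m.role.startswith(prefix)
        }


def generate_session(
    config: SessionConfig,
    model: ProfileModel,
    sensitivities: SensitivityMap,
    geometry: ArrayGeometry,
    grid: GridSpec,
    perturb_schedule: dict[str, PerturbationSpec] | None = None,
) -> SimulatedSession:
    """Simulate every irradiation of the configured measurement plan.

    ``perturb_schedule`` maps roles to per-measurement perturbations; any
    unlisted measurement gets the neutral perturbation with the session's
    global noise level.  All randomness derives from ``config.seed`` via
    per-measurement substreams, so sessions are bit-reproducible.
    """
    schedule = dict(perturb_schedule or {})
    shifts = config.plan_shifts()
    seeds = np.random.SeedSequence(config.seed).spawn(len(shifts))
    measurements = []
    for (role, shift, fieldspec), seed in zip(shifts, seeds):
        perturb = schedule.get(role, NEUTRAL)
        if perturb.noise_sd_rel == 0.0 and config.noise_sd_rel > 0.0:
            perturb = replace(perturb, noise_sd_rel=config.noise_sd_rel)
        wide = fieldspec is config.wide_field
        measurements.append(
            simulate_measurement(
                model,
                sensitivities,
                geometry,
                shift,
                grid,
                fieldspec,
                mu=config.mu,
                perturb=perturb,
                rng=np.random.default_rng(seed),
                narrow_flat=(not wide) and config.narrow_flat,
                expect_wide=wide,
                meta={"role": role, "plan": config.plan},
            )
        )
    return SimulatedSession(
        config=config,
        geometry=geometry,
        grid=grid,
        measurements=measurements,
        model=model,
        sensitivities=sensitivities,
    )
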