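"""Documented text formats and configuration handling.

The measurement format is native to this package (vendor array formats
are proprietary and undocumented): a self-describing header, then a
tab-separated reading matrix with ``NA`` marking masked cells.  All
floats are written with ``repr`` so read(write(m)) round-trips the text
representation bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from .calibration import SensitivityMap
from .geometry import ArrayGeometry, GridSpec
from .simulator import (
    FieldSpec,
    Measurement,
    SessionConfig,
    SimulatedSession,
)

__all__ = [
    "FormatError",
    "MEASUREMENT_FORMAT_VERSION",
    "write_measurement",
    "read_measurement",
    "write_sensitivity_tsv",
    "read_sensitivity_tsv",
    "write_profile",
    "read_profile",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "config_hash",
    "write_session",
    "read_session",
]

MEASUREMENT_FORMAT_VERSION = 1
_MAGIC = "ARRAYCAL-MEASUREMENT"
_KNOWN_KEYS = {
    "geometry", "shift_steps", "field_cm", "field_label", "mu", "meta",
}


class FormatError(ValueError):
    """Malformed file; the message names the offending line."""


def _fmt(x: float) -> str:
    return "NA" if not np.isfinite(x) else repr(float(x))


def write_measurement(m: Measurement, geometry: ArrayGeometry, path) -> None:
    lines = [f"{_MAGIC} {MEASUREMENT_FORMAT_VERSION}"]
    lines.append(f"geometry: {geometry.to_json()}")
    lines.append(f"shift_steps: {m.shift_steps[0]} {m.shift_steps[1]}")
    lines.append(f"field_cm: {repr(m.field.width_cm)} {repr(m.field.height_cm)}")
    lines.append(f"field_label: {m.field.label}")
    lines.append(f"mu: {repr(m.mu)}")
    lines.append(f"meta: {json.dumps(m.meta, sort_keys=True)}")
    lines.append(f"READINGS {geometry.n_rows} {geometry.n_cols}")
    for r in range(geometry.n_rows):
        lines.append("\t".join(_fmt(v) for v in m.readings[r]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_measurement(path) -> tuple[Measurement, ArrayGeometry]:
    """Parse a measurement file; unknown header keys are preserved in the
    measurement's meta (with a warning), malformed content is rejected with
    the line number."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(_MAGIC):
        raise FormatError(f"{path}: line 1: not an {_MAGIC} file")
    version = lines[0][len(_MAGIC):].strip()
    if version != str(MEASUREMENT_FORMAT_VERSION):
        raise FormatError(
            f"{path}: line 1: unsupported format version {version!r} "
            f"(expected {MEASUREMENT_FORMAT_VERSION})"
        )
    header: dict[str, str] = {}
    extra: dict[str, str] = {}
    body_at = None
    for ln, line in enumerate(lines[1:], start=2):
        if line.startswith("READINGS"):
            body_at = ln
            break
        if ":" not in line:
            raise FormatError(f"{path}: line {ln}: expected 'key: value'")
        key, _, value = line.partition(":")
        key = key.strip()
        if key in _KNOWN_KEYS:
            header[key] = value.strip()
        else:
            warnings.warn(f"{path}: line {ln}: unknown header key {key!r} preserved in meta")
            extra[key] = value.strip()
    if body_at is None:
        raise FormatError(f"{path}: missing READINGS section")
    for key in ("geometry", "shift_steps", "field_cm", "mu"):
        if key not in header:
            raise FormatError(f"{path}: missing required header key {key!r}")
    geometry = ArrayGeometry.from_json(header["geometry"])
    try:
        n_rows, n_cols = (int(t) for t in lines[body_at - 1].split()[1:])
    except ValueError as exc:
        raise FormatError(f"{path}: line {body_at}: bad READINGS dimensions") from exc
    if (n_rows, n_cols) != (geometry.n_rows, geometry.n_cols):
        raise FormatError(
            f"{path}: line {body_at}: READINGS shape ({n_rows}, {n_cols}) does "
            f"not match the geometry ({geometry.n_rows}, {geometry.n_cols})"
        )
    body = lines[body_at:]
    if len(body) < n_rows:
        raise FormatError(
            f"{path}: body truncated: {len(body)} rows, expected {n_rows}"
        )
    readings = np.full((n_rows, n_cols), np.nan)
    for r in range(n_rows):
        ln = body_at + 1 + r
        cells = body[r].split("\t")
        if len(cells) != n_cols:
            raise FormatError(
                f"{path}: line {ln}: row has {len(cells)} cells, expected {n_cols}"
            )
        for c, cell in enumerate(cells):
            if cell == "NA":
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: bad value {cell!r}") from exc
            if v < 0:
                raise FormatError(f"{path}: line {ln}: negative reading {cell!r}")
            readings[r, c] = v
    meta = json.loads(header.get("meta", "{}"))
    meta.update(extra)
    w, h = (float(t) for t in header["field_cm"].split())
    sx, sy = (int(t) for t in header["shift_steps"].split())
    return (
        Measurement(
            readings=readings,
            shift_steps=(sx, sy),
            field=FieldSpec(w, h, header.get("field_label", "")),
            mu=float(header["mu"]),
            meta=meta,
        ),
        geometry,
    )


# -- sensitivity maps ---------------------------------------------------------


def write_sensitivity_tsv(
    smap: SensitivityMap, geometry: ArrayGeometry, path, header: dict | None = None
) -> None:
    """TSV with one line per unmasked detector: row, col, x_cm, y_cm, s."""
    x, y = geometry.positions()
    lines = [f"# arraycal sensitivity map v1"]
    lines.append(f"# provenance: {smap.provenance}")
    ni = smap.normalization_index
    lines.append(f"# normalization_detector: {ni[0]} {ni[1]}")
    for k, v in (header or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("row\tcol\tx_cm\ty_cm\ts")
    for r, c in zip(*np.nonzero(geometry.mask)):
        lines.append(
            f"{r}\t{c}\t{repr(float(x[r, c]))}\t{repr(float(y[r, c]))}\t"
            f"{_fmt(smap.values[r, c])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sensitivity_tsv(path, geometry: ArrayGeometry) -> SensitivityMap:
    values = np.full((geometry.n_rows, geometry.n_cols), np.nan)
    norm_index = geometry.origin_index
    provenance = ""
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("# provenance:"):
            provenance = line.partition(":")[2].strip()
            continue
        if line.startswith("# normalization_detector:"):
            norm_index = tuple(int(t) for t in line.partition(":")[2].split())
            continue
        if line.startswith("#") or line.startswith("row\t"):
            continue
        cells = line.split("\t")
        if len(cells) != 5:
            raise FormatError(f"{path}: line {ln}: expected 5 tab-separated cells")
        r, c = int(cells[0]), int(cells[1])
        values[r, c] = np.nan if cells[4] == "NA" else float(cells[4])
    return SensitivityMap(
        values=values, normalization_index=norm_index, provenance=provenance
    )


# -- gridded profiles ---------------------------------------------------------


def write_profile(profile, path) -> None:
    """Gridded text matrix with a header (step sizes, index ranges)."""
    g = profile.grid
    lines = [
        "# arraycal profile v1",
        f"# step_cm: {repr(g.step_x_cm)} {repr(g.step_y_cm)}",
        f"# x_range: {g.x_min} {g.x_max}",
        f"# y_range: {g.y_min} {g.y_max}",
    ]
    for row in profile.values:
        lines.append("\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path):
    from .reconstruction import NormalizedProfile2D

    header: dict[str, str] = {}
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("# ") and ":" in line:
            key, _, value = line[2:].partition(":")
            header[key.strip()] = value.strip()
        elif line.startswith("#"):
            continue
        else:
            rows.append([np.nan if c == "NA" else float(c) for c in line.split("\t")])
    try:
        sx, sy = (float(t) for t in header["step_cm"].split())
        x_min, x_max = (int(t) for t in header["x_range"].split())
        y_min, y_max = (int(t) for t in header["y_range"].split())
    except KeyError as exc:
        raise FormatError(f"{path}: missing profile header key {exc}") from exc
    grid = GridSpec(sx, sy, x_min, x_max, y_min, y_max)
    return NormalizedProfile2D(grid=grid, values=np.array(rows))


# -- session configuration ----------------------------------------------------


def config_to_dict(config: SessionConfig) -> dict:
    doc = dataclasses.asdict(config)
    for key in ("wide_field", "narrow_lat_field", "narrow_lng_field"):
        f = doc[key]
        doc[key] = [f["width_cm"], f["height_cm"], f["label"]]
    return doc


def config_from_dict(doc: dict) -> SessionConfig:
    """Validated SessionConfig from a plain mapping (YAML/JSON).  Unknown
    keys are rejected so typos cannot silently change a plan."""
    doc = dict(doc)
    kwargs = {}
    names = {f.name for f in dataclasses.fields(SessionConfig)}
    unknown = set(doc) - names
    if unknown:
        raise FormatError(f"unknown session config keys: {sorted(unknown)}")
    for key, value in doc.items():
        if key.endswith("_field"):
            value = FieldSpec(*value)
        elif key in ("anchors_lat", "anchors_lng", "scan_lat_range", "scan_lng_range"):
            value = tuple(int(t) for t in value)
        kwargs[key] = value
    return SessionConfig(**kwargs)


def load_config(path) -> SessionConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def config_hash(config: SessionConfig) -> str:
    """Stable short hash identifying a session configuration."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- whole sessions -----------------------------------------------------------


def write_session(session: SimulatedSession, directory) -> Path:
    """Write every measurement, a manifest, and (if present) the ground
    truth of a session to a directory; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, m in enumerate(session.measurements):
        name = f"{i:03d}_{m.role.replace(':', '_') or 'measurement'}.txt"
        write_measurement(m, session.geometry, directory / name)
        entries.append({"file": name, "role": m.role})
    manifest = {
        "format": "arraycal-session v1",
        "config": config_to_dict(session.config),
        "config_hash": config_hash(session.config),
        "grid": {
            "step_cm": [session.grid.step_x_cm, session.grid.step_y_cm],
            "x_range": [session.grid.x_min, session.grid.x_max],
            "y_range": [session.grid.y_min, session.grid.y_max],
        },
        "measurements": entries,
    }
    if session.sensitivities is not None:
        write_sensitivity_tsv(
            session.sensitivities, session.geometry, directory / "truth_sensitivities.tsv"
        )
        manifest["truth_sensitivities"] = "truth_sensitivities.tsv"
    path = directory / "session.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def read_session(directory) -> SimulatedSession:
    """Load a session directory back into memory (ground-truth fields are
    None unless the manifest references them)."""
    directory = Path(directory)
    with open(directory / "session.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = config_from_dict(manifest["config"])
    gdoc = manifest["grid"]
    grid = GridSpec(
        gdoc["step_cm"][0], gdoc["step_cm"][1],
        gdoc["x_range"][0], gdoc["x_range"][1],
        gdoc["y_range"][0], gdoc["y_range"][1],
    )
    measurements, geometry = [], None
    for entry in manifest["measurements"]:
        m, geometry = read_measurement(directory / entry["file"])
        measurements.append(m)
    if geometry is None:
        raise FormatError(f"{directory}: session has no measurements")
    sens = None
    if manifest.get("truth_sensitivities"):
        sens = read_sensitivity_tsv(directory / manifest["truth_sensitivities"], geometry)
    return SimulatedSession(
        config=config,
        geometry=geometry,
        grid=grid,
        measurements=measurements,
        model=None,
        sensitivities=sens,
    )
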