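"""Shared fixtures: small synthetic arrays and sessions.

Most tests run on a 9x9 unstaggered array with a 1 cm grid, which keeps
every chain short while exercising both chain directions, the triad
anchors, and the narrow-field scans.  The full staggered MapCHECK2
layout is used only where the stagger/mask structure is the point.
"""

from __future__ import annotations

import numpy as np
import pytest

from arraycal import (
    FieldSpec,
    ProfileModel,
    SessionConfig,
    build_grid_geometry,
    build_mapcheck2_geometry,
    generate_session,
    mapcheck2_default_grid,
    sample_sensitivities,
)
from arraycal.geometry import GridSpec


@pytest.fixture(scope="session")
def geom9():
    return build_grid_geometry(9, 9, 1.0)


@pytest.fixture(scope="session")
def grid9():
    return GridSpec(1.0, 1.0, -4, 4, -4, 4)


@pytest.fixture(scope="session")
def mapcheck2():
    return build_mapcheck2_geometry()


@pytest.fixture(scope="session")
def mc2_grid():
    return mapcheck2_default_grid()


@pytest.fixture(scope="session")
def bowl():
    return ProfileModel()


@pytest.fixture(scope="session")
def flat():
    return ProfileModel(kind="flat")


def small_config(plan: str = "2dbp_locked", **overrides) -> SessionConfig:
    """Session plan scaled to the 9x9 array: 14 cm wide field, 2 cm strips,
    anchors at +-3 steps, scans covering the grid."""
    defaults = dict(
        plan=plan,
        wide_field=FieldSpec(14.0, 14.0, "wide 14x14"),
        narrow_lat_field=FieldSpec(2.0, 14.0, "narrow 2x14"),
        narrow_lng_field=FieldSpec(14.0, 2.0, "narrow 14x2"),
        anchors_lat=(-3, 3),
        anchors_lng=(-3, 3),
        scan_lat_range=(-4, 4),
        scan_lng_range=(-4, 4),
    )
    defaults.update(overrides)
    return SessionConfig(**defaults)


@pytest.fixture()
def small_session_factory(geom9, grid9, bowl):
    """Callable building a simulated session on the small array."""

    def build(plan="2dbp_locked", model=bowl, sens_spread=0.03, sens_seed=42,
              schedule=None, **overrides):
        config = small_config(plan, **overrides)
        sens = sample_sensitivities(geom9, sens_spread, sens_seed)
        return generate_session(config, model, sens, geom9, grid9, schedule)

    return build


def truth_normalized(session) -> np.ndarray:
    """Ground-truth sensitivities normalized at the origin detector."""
    r0, c0 = session.geometry.origin_index
    return session.sensitivities.values / session.sensitivities.values[r0, c0]
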