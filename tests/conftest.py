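"""Shared fixtures: small constructed records and seeded synthetic scenarios."""

from __future__ import annotations

from datetime import datetime, timezone

import pytest
from hypothesis import settings

from batmove import synth
from batmove.telemetry import Deployment, Detection, Tower

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

#: ~1 km of latitude in degrees on the R=6371 km sphere.
KM_LAT = 1.0 / 111.1949266


def utc(s: str) -> datetime:
    """Parse '2021-09-01 02:00' as a UTC instant."""
    return datetime.fromisoformat(s).replace(tzinfo=timezone.utc)


def mk_det(
    tag="t1",
    ts="2021-09-01 02:00",
    tower="tw1",
    antenna="a1",
    signal=50.0,
    run=5,
) -> Detection:
    t = ts if isinstance(ts, datetime) else utc(ts)
    return Detection(tag, t, tower, antenna, signal, run)


def mk_dep(
    tag="t1",
    release="2021-08-31 23:30",
    lat=37.3,
    lon=-76.0,
    life=30.0,
) -> Deployment:
    t = release if isinstance(release, datetime) else utc(release)
    return Deployment(tag, "LABO", "male", "adult", t, lat, lon, life)


def tower_at_km(tower_id: str, origin_lat: float, origin_lon: float, north_km: float, sides=None) -> Tower:
    """A tower displaced due north of an origin by a exact whole-km arc."""
    return Tower(tower_id, origin_lat + north_km * KM_LAT, origin_lon, sides or {})


@pytest.fixture(scope="session")
def default_scenario():
    """The generator's default study conditions (seeded)."""
    return synth.simulate_scenario(synth.ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_scenario_config():
    """A reduced cohort for fast pipeline runs."""
    return synth.ScenarioConfig(
        seed=2,
        n_towers=12,
        n_bats_by_archetype={"resident": 3, "migrant": 2, "crosser": 3, "returner": 1},
    )
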