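"""Core domain types, geodesy/solar utilities, CSV I/O, and detection cleaning.

Automated VHF radiotelemetry networks (Motus-style) log timestamped tag
detections at fixed receiver towers.  Raw detection tables contain false
positives (radio noise decoded as short runs, impossibly distant towers) and
tag-drop artefacts (a shed transmitter lying in range of a tower produces a
long, steady signal).  This module provides the record types for detections,
towers and tag deployments, great-circle geometry, NOAA sunset arithmetic,
and the rule-based cleaning filters applied before any behavioural inference:

* run-length filter — keep only detection runs longer than 3 sequential hits;
* implausibility filter — drop detections at towers more than 1,000 km from
  both the release point and the neighbouring retained detections;
* tag-drop trim — remove a terminal segment whose signal strength stays
  steady for at least 7 days at a single tower/antenna.

All timestamps are stored timezone-aware UTC; coordinates are WGS84 decimal
degrees; distances use a spherical Earth of radius 6371.0 km.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Solar zenith angle (degrees) defining standard sunrise/sunset: 90° plus
#: 34' of atmospheric refraction plus 16' of solar semi-diameter.
SUNSET_ZENITH_DEG = 90.833

__all__ = [
    "EARTH_RADIUS_KM",
    "SUNSET_ZENITH_DEG",
    "Detection",
    "Tower",
    "Deployment",
    "Track",
    "haversine_km",
    "initial_bearing_deg",
    "sunset_utc",
    "sunrise_utc",
    "hours_since_sunset",
    "night_id",
    "is_night",
    "cyclical_hour",
    "filter_run_length",
    "filter_implausible",
    "trim_tag_drop",
    "build_tracks",
    "read_detections",
    "write_detections",
    "read_towers",
    "write_towers",
    "read_deployments",
    "write_deployments",
    "detections_to_frame",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Detection:
    """One timestamped detection of a tag at a tower antenna.

    ``run_length`` is the number of sequential detections in the reception
    run this record belongs to; runs of three or fewer are treated as likely
    radio noise by :func:`filter_run_length`.
    """

    tag_id: str
    timestamp: datetime
    tower_id: str
    antenna_id: str
    signal_strength: float
    run_length: int

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ValueError(f"Detection timestamp must be timezone-aware: {self.timestamp!r}")
        if self.run_length < 1:
            raise ValueError(f"run_length must be >= 1, got {self.run_length}")


@dataclass(frozen=True)
class Tower:
    """A fixed receiver tower.

    ``water_sides`` maps a water-body name to the side label the tower sits
    on (e.g. ``{"chesapeake": "east"}``).  Side labels are declared input
    metadata — each water body has exactly two legal labels — and stand in
    for the spatial judgement of which shore a tower occupies.
    """

    tower_id: str
    lat: float
    lon: float
    water_sides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"tower {self.tower_id}: invalid coordinates ({self.lat}, {self.lon})")


@dataclass(frozen=True)
class Deployment:
    """Release metadata for one tagged individual."""

    tag_id: str
    species: str
    sex: str
    age: str
    release_time: datetime
    release_lat: float
    release_lon: float
    tag_life_days: float = 30.0

    def __post_init__(self) -> None:
        if self.release_time.tzinfo is None:
            raise ValueError("release_time must be timezone-aware")
        if not (-90.0 <= self.release_lat <= 90.0 and -180.0 <= self.release_lon <= 180.0):
            raise ValueError(f"deployment {self.tag_id}: invalid release coordinates")
        if self.tag_life_days <= 0:
            raise ValueError("tag_life_days must be positive")


@dataclass
class Track:
    """A tag's time-ordered detections together with its deployment."""

    tag_id: str
    detections: list[Detection]
    deployment: Deployment

    def __post_init__(self) -> None:
        self.detections = sorted(self.detections, key=lambda d: d.timestamp)


# ---------------------------------------------------------------------------
# Geodesy
# ---------------------------------------------------------------------------


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0 km."""
    for v in (lat1, lon1, lat2, lon2):
        if not math.isfinite(v):
            raise ValueError("haversine_km: non-finite coordinate")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def initial_bearing_deg(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Initial great-circle bearing from point 1 to point 2.

    Returns degrees in [0, 360), 0 = north, clockwise.  Raises for
    coincident points, where the bearing is undefined.
    """
    if math.isclose(lat1, lat2, abs_tol=1e-12) and math.isclose(lon1, lon2, abs_tol=1e-12):
        raise ValueError("initial_bearing_deg: coincident points, bearing undefined")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    x = math.sin(dl) * math.cos(p2)
    y = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    deg = math.degrees(math.atan2(x, y)) % 360.0
    return 0.0 if deg >= 360.0 else deg


# ---------------------------------------------------------------------------
# Solar time (NOAA solar-position approximation)
# ---------------------------------------------------------------------------
# Formulas follow the NOAA solar calculator: Julian-century polynomial for
# the sun's geometric mean longitude/anomaly, equation of centre, apparent
# longitude corrected for nutation, obliquity, equation of time, and the
# hour angle at zenith 90.833 degrees.


def _julian_day(d: date) -> float:
    y, m = d.year, d.month
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d.day + b - 1524.5


def _solar_noon_decl_eqtime(d: date, lon: float) -> tuple[float, float, float]:
    """(solar noon UTC minutes, declination rad, equation of time minutes)."""
    jd = _julian_day(d) + 0.5  # noon of the civil date
    jc = (jd - 2451545.0) / 36525.0
    gml = math.radians((280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0)
    gma = math.radians(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eqc = (
        math.sin(gma) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * gma) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * gma) * 0.000289
    )
    true_long = math.degrees(gml) + eqc
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = math.radians(mean_obliq + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(obliq) * math.sin(app_long))
    var_y = math.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * gml)
        - 2.0 * ecc * math.sin(gma)
        + 4.0 * ecc * var_y * math.sin(gma) * math.cos(2 * gml)
        - 0.5 * var_y * var_y * math.sin(4 * gml)
        - 1.25 * ecc * ecc * math.sin(2 * gma)
    )
    solar_noon_min = 720.0 - 4.0 * lon - eqtime
    return solar_noon_min, decl, eqtime


@lru_cache(maxsize=262144)
def _sun_event_utc(d: date, lat: float, lon: float, *, rising: bool) -> datetime:
    noon_min, decl, _ = _solar_noon_decl_eqtime(d, lon)
    phi = math.radians(lat)
    cos_ha = (
        math.cos(math.radians(SUNSET_ZENITH_DEG)) / (math.cos(phi) * math.cos(decl))
        - math.tan(phi) * math.tan(decl)
    )
    if not (-1.0 < cos_ha < 1.0):
        raise ValueError(
            f"sun never rises/sets at lat={lat} on {d} (polar day or night); out of study domain"
        )
    ha_min = 4.0 * math.degrees(math.acos(cos_ha))
    minutes = noon_min - ha_min if rising else noon_min + ha_min
    base = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    return base + timedelta(minutes=minutes)


def sunset_utc(d: date, lat: float, lon: float) -> datetime:
    """UTC instant of sunset on civil date ``d`` at the given location."""
    return _sun_event_utc(d, lat, lon, rising=False)


def sunrise_utc(d: date, lat: float, lon: float) -> datetime:
    """UTC instant of sunrise on civil date ``d`` at the given location."""
    return _sun_event_utc(d, lat, lon, rising=True)


def _as_utc(ts: datetime) -> datetime:
    if ts.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    return ts.astimezone(timezone.utc)


def _previous_sunset(ts: datetime, lat: float, lon: float) -> datetime:
    ts = _as_utc(ts)
    for back in (0, 1, 2):
        d = (ts - timedelta(days=back)).date()
        s = sunset_utc(d, lat, lon)
        if s <= ts:
            return s
    raise RuntimeError("no sunset found in the previous two days")  # pragma: no cover


def hours_since_sunset(ts: datetime, lat: float, lon: float) -> float:
    """Hours elapsed since the most recent local sunset before ``ts``."""
    s = _previous_sunset(ts, lat, lon)
    return (_as_utc(ts) - s).total_seconds() / 3600.0


def is_night(ts: datetime, lat: float, lon: float) -> bool:
    """True when the sun is below the standard sunset zenith at ``ts``."""
    s = _previous_sunset(ts, lat, lon)
    nxt = s.date()
    # sunrise following that sunset is on the same or the next civil date
    r = sunrise_utc(nxt, lat, lon)
    if r <= s:
        r = sunrise_utc(nxt + timedelta(days=1), lat, lon)
    return _as_utc(ts) < r


def night_id(ts: datetime, lat: float, lon: float) -> date:
    """Calendar date labelling the night ``ts`` belongs to.

    Every instant between a sunset and the following sunrise carries the
    sunset's civil date; a daytime instant carries the date of the upcoming
    sunset, so the label increments by one day at each sunrise.
    """
    s = _previous_sunset(ts, lat, lon)
    if is_night(ts, lat, lon):
        return s.date()
    return s.date() + timedelta(days=1)


def cyclical_hour(h: float) -> tuple[float, float]:
    """Sine/cosine encoding of an hour-of-cycle value on a 24-h period.

    Maps ``h`` in [0, 24) to ``(sin(2*pi*h/24), cos(2*pi*h/24))``, both in
    [-1, 1], so that hour 0 and hour 24 are adjacent in covariate space.
    """
    if not (0.0 <= h < 24.0):
        raise ValueError(f"cyclical_hour: h must be in [0, 24), got {h}")
    ang = 2.0 * math.pi * h / 24.0
    return math.sin(ang), math.cos(ang)


# ---------------------------------------------------------------------------
# Cleaning filters
# ---------------------------------------------------------------------------


def filter_run_length(detections: Sequence[Detection], min_run: int = 4) -> list[Detection]:
    """Drop detections from short runs: only ``run_length >= min_run`` kept.

    The default keeps runs strictly longer than 3 sequential detections;
    shorter runs are likely decoder noise.
    """
    return [d for d in detections if d.run_length >= min_run]


def _tower_index(towers: Iterable[Tower]) -> dict[str, Tower]:
    return {t.tower_id: t for t in towers}


def filter_implausible(track: Track, towers: Iterable[Tower], max_km: float = 1000.0) -> Track:
    """Remove detections at towers implausibly far from the rest of the track.

    A detection is removed when its tower is more than ``max_km`` from the
    release point AND more than ``max_km`` from the towers of both retained
    temporal neighbours.  Applied to a fixed point, so a lone spurious hit
    thousands of km away goes while genuine long hops anchored to the release
    point or to each other stay.
    """
    idx = _tower_index(towers)
    for d in track.detections:
        if d.tower_id not in idx:
            raise KeyError(f"filter_implausible: unknown tower_id {d.tower_id!r}")
    dep = track.deployment
    kept = list(track.detections)
    changed = True
    while changed:
        changed = False
        survivors: list[Detection] = []
        for i, d in enumerate(kept):
            tw = idx[d.tower_id]
            if haversine_km(tw.lat, tw.lon, dep.release_lat, dep.release_lon) <= max_km:
                survivors.append(d)
                continue
            near_neighbor = False
            for j in (i - 1, i + 1):
                if 0 <= j < len(kept):
                    nb = idx[kept[j].tower_id]
                    if haversine_km(tw.lat, tw.lon, nb.lat, nb.lon) <= max_km:
                        near_neighbor = True
                        break
            if near_neighbor:
                survivors.append(d)
            else:
                changed = True
        kept = survivors
    return Track(track.tag_id, kept, dep)


def trim_tag_drop(
    track: Track,
    steady_days: float = 7.0,
    steady_sd_tol: float | None = None,
) -> Track:
    """Trim a terminal steady-signal segment consistent with a shed tag.

    If the final contiguous run of detections at a single tower/antenna spans
    at least ``steady_days`` and its signal-strength standard deviation is at
    most ``steady_sd_tol`` (default: 5% of the whole-track signal SD), the
    segment is removed.  A transmitter lying on the ground emits a steady
    signal; a bat's signal varies with posture and position.
    """
    dets = track.detections
    if len(dets) < 2:
        return Track(track.tag_id, list(dets), track.deployment)
    if steady_sd_tol is None:
        overall_sd = float(np.std([d.signal_strength for d in dets]))
        steady_sd_tol = 0.05 * overall_sd
    last = dets[-1]
    i = len(dets) - 1
    while i > 0 and (dets[i - 1].tower_id, dets[i - 1].antenna_id) == (last.tower_id, last.antenna_id):
        i -= 1
    segment = dets[i:]
    span_days = (segment[-1].timestamp - segment[0].timestamp).total_seconds() / 86400.0
    seg_sd = float(np.std([d.signal_strength for d in segment]))
    if span_days >= steady_days and seg_sd <= steady_sd_tol:
        return Track(track.tag_id, dets[:i], track.deployment)
    return Track(track.tag_id, list(dets), track.deployment)


def build_tracks(
    detections: Sequence[Detection], deployments: Sequence[Deployment]
) -> list[Track]:
    """Group detections by tag into time-ordered tracks.

    Detections before a tag's release time are discarded (clock noise);
    detections for unknown tags raise.
    """
    by_tag: dict[str, list[Detection]] = {}
    for d in detections:
        by_tag.setdefault(d.tag_id, []).append(d)
    dep_idx = {dep.tag_id: dep for dep in deployments}
    unknown = set(by_tag) - set(dep_idx)
    if unknown:
        raise KeyError(f"detections reference undeployed tags: {sorted(unknown)}")
    tracks = []
    for dep in deployments:
        dets = [d for d in by_tag.get(dep.tag_id, []) if d.timestamp >= dep.release_time]
        tracks.append(Track(dep.tag_id, dets, dep))
    return tracks


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_DET_COLS = ["tag_id", "timestamp", "tower_id", "antenna_id", "signal_strength", "run_length"]
_TOWER_COLS = ["tower_id", "lat", "lon", "water_body", "side"]
_DEP_COLS = [
    "tag_id",
    "species",
    "sex",
    "age",
    "release_time",
    "release_lat",
    "release_lon",
    "tag_life_days",
]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df.columns[df.columns.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate column(s) {dup}")


def _parse_utc(series: pd.Series, path, col: str) -> pd.Series:
    out = pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: unparseable {col} at data row {row}: {series.iloc[row]!r}")
    return out


def read_detections(path) -> list[Detection]:
    df = pd.read_csv(path)
    _check_columns(df, _DET_COLS, path)
    ts = _parse_utc(df["timestamp"], path, "timestamp")
    return [
        Detection(
            tag_id=str(r.tag_id),
            timestamp=t.to_pydatetime(),
            tower_id=str(r.tower_id),
            antenna_id=str(r.antenna_id),
            signal_strength=float(r.signal_strength),
            run_length=int(r.run_length),
        )
        for r, t in zip(df.itertuples(index=False), ts)
    ]


def write_detections(detections: Sequence[Detection], path) -> None:
    df = detections_to_frame(detections)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False)


def detections_to_frame(detections: Sequence[Detection]) -> pd.DataFrame:
    """Tabular view of a detection list (timestamps tz-aware UTC)."""
    return pd.DataFrame(
        {
            "tag_id": [d.tag_id for d in detections],
            "timestamp": pd.DatetimeIndex([d.timestamp for d in detections], tz="UTC")
            if detections
            else pd.DatetimeIndex([], tz="UTC"),
            "tower_id": [d.tower_id for d in detections],
            "antenna_id": [d.antenna_id for d in detections],
            "signal_strength": [d.signal_strength for d in detections],
            "run_length": [d.run_length for d in detections],
        }
    )


def read_towers(path) -> list[Tower]:
    """Read towers from CSV: one row per tower-waterbody adjacency."""
    df = pd.read_csv(path)
    _check_columns(df, _TOWER_COLS, path)
    towers: dict[str, dict] = {}
    for i, r in enumerate(df.itertuples(index=False)):
        tid = str(r.tower_id)
        entry = towers.setdefault(tid, {"lat": float(r.lat), "lon": float(r.lon), "sides": {}})
        if not (math.isclose(entry["lat"], float(r.lat)) and math.isclose(entry["lon"], float(r.lon))):
            raise ValueError(f"{path}: tower {tid} has conflicting coordinates at data row {i}")
        wb = r.water_body
        if isinstance(wb, str) and wb:
            entry["sides"][wb] = str(r.side)
    return [Tower(tid, e["lat"], e["lon"], e["sides"]) for tid, e in towers.items()]


def write_towers(towers: Sequence[Tower], path) -> None:
    rows = []
    for t in towers:
        if t.water_sides:
            for wb, side in sorted(t.water_sides.items()):
                rows.append((t.tower_id, t.lat, t.lon, wb, side))
        else:
            rows.append((t.tower_id, t.lat, t.lon, "", ""))
    pd.DataFrame(rows, columns=_TOWER_COLS).to_csv(path, index=False)


def read_deployments(path) -> list[Deployment]:
    df = pd.read_csv(path)
    _check_columns(df, _DEP_COLS, path)
    ts = _parse_utc(df["release_time"], path, "release_time")
    return [
        Deployment(
            tag_id=str(r.tag_id),
            species=str(r.species),
            sex=str(r.sex),
            age=str(r.age),
            release_time=t.to_pydatetime(),
            release_lat=float(r.release_lat),
            release_lon=float(r.release_lon),
            tag_life_days=float(r.tag_life_days),
        )
        for r, t in zip(df.itertuples(index=False), ts)
    ]


def write_deployments(deployments: Sequence[Deployment], path) -> None:
    df = pd.DataFrame(
        {
            "tag_id": [d.tag_id for d in deployments],
            "species": [d.species for d in deployments],
            "sex": [d.sex for d in deployments],
            "age": [d.age for d in deployments],
            "release_time": [
                d.release_time.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
                for d in deployments
            ],
            "release_lat": [d.release_lat for d in deployments],
            "release_lon": [d.release_lon for d in deployments],
            "tag_life_days": [d.tag_life_days for d in deployments],
        }
    )
    df.to_csv(path, index=False)
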