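"""Seeded synthetic telemetry scenarios with ground-truth behaviour labels.

The generator emulates a fall study of migratory tree bats on a coastal
plain: a network of receiver towers flanking two water bodies (towers detect
tags out to ~12 km), hourly weather with diurnal and frontal structure, and
a cohort of tagged bats drawn from four behavioural archetypes —

* ``resident``  — stays within 10 km of the release point, resting by day
  and foraging in nightly activity bouts;
* ``migrant``   — departs after one to three nights on a heading drawn near
  230° (the southwesterly fall direction) and keeps going;
* ``crosser``   — a resident on one shore whose probability of a same-night
  transit across the bay each hour follows a logistic model in atmospheric
  covariates (``crossing_beta``) — the recovery target for the
  use-availability stage;
* ``returner``  — makes one >50 km excursion to a distant tower and comes
  back to the tagging site.

Every stream (weather, trajectories, detections) is independently
reproducible from ``(seed, config)``.  Truth labels record the *realised*
behaviour: a crosser that never happened to transit the bay is labelled a
resident, because no classifier — and no field biologist — could tell the
difference from detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .telemetry import (
    Deployment,
    Detection,
    Tower,
    cyclical_hour,
    haversine_km,
    hours_since_sunset,
    initial_bearing_deg,
    sunset_utc,
)

__all__ = [
    "ScenarioConfig",
    "TruthLabel",
    "make_towers",
    "simulate_weather",
    "simulate_bats",
    "simulate_detections",
    "simulate_scenario",
    "simulate_hmm_series",
    "simulate_crossing_hours",
    "read_weather",
    "write_weather",
    "write_truth",
    "read_truth",
]

KM_PER_DEG_LAT = 111.2


def _default_archetypes() -> dict[str, int]:
    return {"resident": 14, "migrant": 10, "crosser": 12, "returner": 4}


def _default_crossing_beta() -> dict[str, float]:
    # Signs and magnitudes follow the field estimates for over-water flight:
    # transits early in the night, in light winds, on warm nights.
    return {
        "intercept": -6.0,
        "hours_since_sunset": -0.35,
        "wind_speed": -0.30,
        "temperature": 0.12,
    }


def _default_hmm_truth() -> dict:
    # Scaled hourly signal-SD emissions: the two state means sit ~3 pooled
    # SDs apart so decoding is feasible but not trivial.
    return {
        "mu_rest": 0.25,
        "sd_rest": 0.12,
        "mu_active": 0.90,
        "sd_active": 0.30,
        # logit P(next = active | prev = state), design [1, sin, cos] of
        # hours-since-sunset on a 24-h cycle.  The sin+cos mix peaks shortly
        # after sunset and declines through the night, so activity is most
        # likely in the early night hours and rest dominates by day.
        "trans_from_rest": (-1.0, 2.5, 2.0),
        "trans_from_active": (1.2, 2.5, 2.0),
        "temp_coef": 0.15,  # extra pull toward "active" per deg C above season mean
    }


@dataclass
class ScenarioConfig:
    """Configuration for one synthetic study scenario."""

    seed: int = 0
    n_towers: int = 16
    detection_range_km: float = 12.0
    full_detection_km: float = 6.0
    n_bats_by_archetype: dict[str, int] = field(default_factory=_default_archetypes)
    study_start: date = date(2021, 8, 15)
    study_end: date = date(2021, 10, 15)
    crossing_beta: dict[str, float] = field(default_factory=_default_crossing_beta)
    hmm_truth: dict = field(default_factory=_default_hmm_truth)
    # signal model: strength = signal_s0 - signal_k * ln(d_km + 1) + noise
    signal_s0: float = 60.0
    signal_k: float = 15.0
    signal_sd_rest: float = 1.0
    signal_sd_active: float = 6.0
    tag_drop_prob: float = 0.1
    noise_run_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.detection_range_km <= 0:
            raise ValueError("detection_range_km must be positive")
        if any(v < 0 for v in self.n_bats_by_archetype.values()):
            raise ValueError("archetype counts must be >= 0")
        for key in ("sd_rest", "sd_active"):
            if self.hmm_truth[key] <= 0:
                raise ValueError(f"hmm_truth[{key!r}] must be positive")
        if self.n_towers < 12:
            raise ValueError("n_towers must be >= 12 (ten bay towers plus inland scatter)")


@dataclass
class TruthLabel:
    """Ground-truth record for one simulated tag (the acceptance oracle)."""

    tag_id: str
    archetype: str
    drawn_heading_deg: float | None = None
    true_crossing_nights: list[date] = field(default_factory=list)
    hourly_state: pd.Series | None = None  # index: UTC hour, values {"rest","active"}


# ---------------------------------------------------------------------------
# Tower network
# ---------------------------------------------------------------------------

_BAY_TOWERS = [
    # tower_id suffix, lat, lon, water body, side
    ("ch_w1", 37.00, -76.40, "chesapeake", "west"),
    ("ch_w2", 37.50, -76.40, "chesapeake", "west"),
    ("ch_w3", 38.00, -76.40, "chesapeake", "west"),
    ("ch_e1", 37.10, -76.00, "chesapeake", "east"),
    ("ch_e2", 37.60, -76.00, "chesapeake", "east"),
    ("ch_e3", 38.10, -76.00, "chesapeake", "east"),
    ("de_w1", 38.60, -75.30, "delaware", "west"),
    ("de_w2", 39.00, -75.30, "delaware", "west"),
    ("de_e1", 38.70, -74.90, "delaware", "east"),
    ("de_e2", 39.10, -74.90, "delaware", "east"),
]


def make_towers(config: ScenarioConfig) -> list[Tower]:
    """Tower network: ten towers flanking two bays plus inland scatter.

    The bays run north-south; opposite-shore towers sit ~35 km apart, wide
    enough that a transit is unambiguous but below the 50-km migration
    threshold.  Inland towers scatter over the landmass southwest of the
    network so migrating bats on southwesterly headings pass within range.
    """
    towers = [Tower(tid, lat, lon, {wb: side}) for tid, lat, lon, wb, side in _BAY_TOWERS]
    rng = np.random.default_rng([config.seed, 11])
    for i in range(config.n_towers - len(_BAY_TOWERS)):
        lat = float(rng.uniform(36.0, 37.6))
        lon = float(rng.uniform(-78.5, -77.0))
        towers.append(Tower(f"in_{i+1}", lat, lon, {}))
    return towers


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

STATION_ID = "wx0"
STATION_LAT = 37.8
STATION_LON = -76.2

WEATHER_COLS = [
    "station_id",
    "timestamp",
    "temperature",
    "wind_speed",
    "wind_dir",
    "pressure",
    "precipitation",
    "visibility",
]

#: AR(1) coefficient for the hourly temperature residual process.
TEMP_AR1 = 0.8


def simulate_weather(config: ScenarioConfig) -> pd.DataFrame:
    """Hourly weather at a single collocated station.

    temperature  seasonal linear decline + diurnal sinusoid + AR(1) noise
    wind_speed   exponentiated AR(1) (always positive), median ~3 m/s
    wind_dir     wrapped random walk (degrees the wind blows FROM)
    pressure     AR(1) around 101.3 kPa with occasional frontal steps
    precipitation  sparse multi-hour bursts (accumulated cm)
    visibility   16 km minus a precipitation-coupled reduction, clamped
    """
    if config.study_end <= config.study_start:
        raise ValueError("study_end must be after study_start")
    rng = np.random.default_rng([config.seed, 12])
    start = datetime.combine(config.study_start - timedelta(days=2), time(0), timezone.utc)
    end = datetime.combine(config.study_end + timedelta(days=1), time(0), timezone.utc)
    hours = pd.date_range(start, end, freq="h", inclusive="left")
    n = len(hours)
    days = (hours - hours[0]).total_seconds().to_numpy() / 86400.0
    hour_utc = hours.hour.to_numpy()

    season = 22.0 - 12.0 * days / max(days[-1], 1.0)
    diurnal = 4.0 * np.cos(2.0 * np.pi * (hour_utc - 19.0) / 24.0)  # peak ~14:00 local
    ar = np.empty(n)
    ar[0] = rng.normal(0.0, 1.2)
    eps = rng.normal(0.0, 1.2 * math.sqrt(1.0 - TEMP_AR1**2), n)
    for t in range(1, n):
        ar[t] = TEMP_AR1 * ar[t - 1] + eps[t]
    temperature = season + diurnal + ar

    lw = np.empty(n)
    lw[0] = math.log(3.0)
    weps = rng.normal(0.0, 0.18, n)
    for t in range(1, n):
        lw[t] = math.log(3.0) + 0.85 * (lw[t - 1] - math.log(3.0)) + weps[t]
    wind_speed = np.exp(lw)

    wind_dir = np.cumsum(rng.normal(0.0, 20.0, n)) + rng.uniform(0.0, 360.0)
    wind_dir = np.mod(wind_dir, 360.0)

    press_ar = np.empty(n)
    press_ar[0] = 0.0
    peps = rng.normal(0.0, 0.02, n)
    fronts = np.where(rng.random(n) < 0.01, rng.normal(0.0, 0.4, n), 0.0)
    front_level = np.cumsum(fronts)
    front_level -= front_level.mean()
    for t in range(1, n):
        press_ar[t] = 0.95 * press_ar[t - 1] + peps[t]
    pressure = 101.3 + press_ar + front_level

    precipitation = np.zeros(n)
    t = 0
    while t < n:
        if rng.random() < 0.01:
            burst = int(rng.integers(2, 9))
            for j in range(burst):
                if t + j < n:
                    precipitation[t + j] = rng.exponential(0.15)
            t += burst
        else:
            t += 1

    visibility = np.clip(16.0 - 40.0 * precipitation - np.abs(rng.normal(0.0, 0.5, n)), 0.0, 16.0)

    return pd.DataFrame(
        {
            "station_id": STATION_ID,
            "timestamp": hours,
            "temperature": temperature,
            "wind_speed": wind_speed,
            "wind_dir": wind_dir,
            "pressure": pressure,
            "precipitation": precipitation,
            "visibility": visibility,
        }
    )


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df


def write_weather(weather: pd.DataFrame, path) -> None:
    out = weather.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Bat trajectories
# ---------------------------------------------------------------------------


def _move(lat: float, lon: float, bearing_deg: float, dist_km: float) -> tuple[float, float]:
    """Flat-earth step, adequate for the sub-degree hops simulated here."""
    b = math.radians(bearing_deg)
    dlat = dist_km * math.cos(b) / KM_PER_DEG_LAT
    dlon = dist_km * math.sin(b) / (KM_PER_DEG_LAT * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x > -500 else 0.0


class _SolarCache:
    """Memoised hours-since-sunset on a coarse (date, lat, lon) grid."""

    def __init__(self) -> None:
        self._sunsets: dict[tuple[date, float, float], datetime] = {}

    def hss(self, ts: datetime, lat: float, lon: float) -> float:
        la, lo = round(lat, 1), round(lon, 1)
        for back in (0, 1):
            d = (ts - timedelta(days=back)).date()
            key = (d, la, lo)
            if key not in self._sunsets:
                self._sunsets[key] = sunset_utc(d, la, lo)
            s = self._sunsets[key]
            if s <= ts:
                return (ts - s).total_seconds() / 3600.0
        raise RuntimeError("no recent sunset found")  # pragma: no cover


def simulate_bats(
    config: ScenarioConfig, towers: Sequence[Tower], weather: pd.DataFrame
) -> tuple[list[Deployment], pd.DataFrame, list[TruthLabel]]:
    """Simulate hourly ground-truth positions and states for the cohort.

    Returns ``(deployments, positions, truth_labels)`` where ``positions``
    has one row per bat-hour with columns ``tag_id, timestamp, lat, lon,
    state``.
    """
    if sum(config.n_bats_by_archetype.values()) == 0:
        raise ValueError("at least one archetype count must be positive")
    bodies = {wb for t in towers for wb in t.water_sides}
    for wb in bodies:
        sides = {t.water_sides[wb] for t in towers if wb in t.water_sides}
        if len(sides) != 2:
            raise ValueError(f"water body {wb!r} needs towers on both sides")
    if not bodies:
        raise ValueError("towers include no water-body sides")

    rng = np.random.default_rng([config.seed, 13])
    solar = _SolarCache()
    wx = weather.set_index("timestamp")
    wx_temp = wx["temperature"]
    wx_wind = wx["wind_speed"]
    season_mean_temp = float(weather["temperature"].mean())

    east_bay = [t for t in towers if t.water_sides.get("chesapeake") == "east"]
    all_release_sites = east_bay + [t for t in towers if not t.water_sides]
    inland = [t for t in towers if not t.water_sides]

    ht = config.hmm_truth
    c_rest = np.asarray(ht["trans_from_rest"], dtype=float)
    c_active = np.asarray(ht["trans_from_active"], dtype=float)
    temp_coef = float(ht.get("temp_coef", 0.0))

    cb = config.crossing_beta

    deployments: list[Deployment] = []
    truth: list[TruthLabel] = []
    pos_rows: list[tuple] = []

    bat_specs: list[str] = []
    for arch, count in config.n_bats_by_archetype.items():
        bat_specs.extend([arch] * count)

    for k, arch in enumerate(bat_specs):
        tag_id = f"tag{k:03d}"
        if arch in ("resident", "crosser"):
            site = east_bay[int(rng.integers(len(east_bay)))]
        elif arch == "migrant":
            site = east_bay[int(rng.integers(len(east_bay)))]
        else:  # returner
            site = east_bay[int(rng.integers(len(east_bay)))]
        rel_lat, rel_lon = _move(
            site.lat, site.lon, float(rng.uniform(0, 360)), float(rng.uniform(0.5, 3.0))
        )
        release_day = config.study_start + timedelta(days=int(rng.integers(0, 11)))
        release_time = sunset_utc(release_day, rel_lat, rel_lon) + timedelta(minutes=30)
        life_days = float(rng.uniform(15.0, 30.0))
        last_allowed = datetime.combine(config.study_end, time(0), timezone.utc)
        life_days = min(life_days, (last_allowed - release_time).total_seconds() / 86400.0 - 1.0)
        sex = "female" if rng.random() < 0.35 else "male"
        age = "adult" if rng.random() < 0.65 else "juvenile"
        deployments.append(
            Deployment(tag_id, "LABO", sex, age, release_time, rel_lat, rel_lon, life_days)
        )

        # migration / return targets
        drawn_heading: float | None = None
        target: Tower | None = None
        if arch == "migrant":
            drawn_heading = float(rng.normal(230.0, 15.0))
            candidates = [
                t
                for t in towers
                if 50.0 < haversine_km(rel_lat, rel_lon, t.lat, t.lon) < 260.0
            ]
            target = min(
                candidates,
                key=lambda t: abs(
                    (initial_bearing_deg(rel_lat, rel_lon, t.lat, t.lon) - drawn_heading + 180.0)
                    % 360.0
                    - 180.0
                ),
            )
            drawn_heading = initial_bearing_deg(rel_lat, rel_lon, target.lat, target.lon) + float(
                rng.normal(0.0, 3.0)
            )
        elif arch == "returner":
            candidates = [
                t for t in inland if haversine_km(rel_lat, rel_lon, t.lat, t.lon) > 55.0
            ]
            target = candidates[int(rng.integers(len(candidates)))]

        # crosser geometry: origin/destination roosts on opposite shores
        origin_roost = (rel_lat, rel_lon)
        cross_dest: tuple[float, float] | None = None
        if arch == "crosser":
            wb = "chesapeake"
            my_side = site.water_sides[wb]
            opposite = [
                t for t in towers if wb in t.water_sides and t.water_sides[wb] != my_side
            ]
            dest_tower = min(opposite, key=lambda t: haversine_km(rel_lat, rel_lon, t.lat, t.lon))
            cross_dest = _move(
                dest_tower.lat,
                dest_tower.lon,
                float(rng.uniform(0, 360)),
                float(rng.uniform(0.5, 2.5)),
            )

        n_hours = int(life_days * 24)
        start_hour = release_time.replace(minute=0, second=0, microsecond=0) + timedelta(hours=1)
        hours = [start_hour + timedelta(hours=h) for h in range(n_hours)]

        pre_nights = int(rng.integers(1, 4))
        depart_after = release_time + timedelta(days=pre_nights)

        roost = origin_roost
        cur = roost
        state = 0  # 0 rest, 1 active
        mode = "resident"
        crossing_nights: list[date] = []
        cross_path: list[tuple[float, float]] = []
        away_until: datetime | None = None
        returning = False
        settled = False
        states_out: list[str] = []

        for ts in hours:
            hss = solar.hss(ts, cur[0], cur[1])
            sin_h, cos_h = cyclical_hour(hss % 24.0)
            hour_stamp = ts
            try:
                temp = float(wx_temp.loc[hour_stamp])
                wind = float(wx_wind.loc[hour_stamp])
            except KeyError:  # pragma: no cover - weather always covers life
                temp, wind = season_mean_temp, 3.0

            # latent rest/active state (covariate-transition Markov chain)
            coefs = c_active if state == 1 else c_rest
            eta = coefs[0] + coefs[1] * sin_h + coefs[2] * cos_h + temp_coef * (
                temp - season_mean_temp
            )
            state = 1 if rng.random() < _sigmoid(eta) else 0

            if arch == "migrant" and mode == "resident" and ts >= depart_after and hss < 1.5:
                mode = "travel"
            if (
                arch == "returner"
                and mode == "resident"
                and not returning
                and ts >= depart_after
                and hss < 1.5
            ):
                mode = "travel"

            if mode == "travel" and target is not None:
                if hss < 10.0:  # travels by night
                    state = 1
                    goal = origin_roost if returning else (target.lat, target.lon)
                    dist_to_goal = haversine_km(cur[0], cur[1], goal[0], goal[1])
                    step = min(25.0, dist_to_goal)
                    brg = initial_bearing_deg(cur[0], cur[1], goal[0], goal[1]) if dist_to_goal > 0.5 else 0.0
                    cur = _move(cur[0], cur[1], brg + float(rng.normal(0.0, 4.0)), step)
                    cur = (
                        cur[0] + float(rng.normal(0.0, 0.005)),
                        cur[1] + float(rng.normal(0.0, 0.005)),
                    )
                    if haversine_km(cur[0], cur[1], goal[0], goal[1]) < 2.0:
                        if arch == "migrant" and not settled:
                            # keep going past the target, then settle out of range
                            target_beyond = _move(cur[0], cur[1], drawn_heading, 30.0)
                            target = Tower("_virtual", target_beyond[0], target_beyond[1], {})
                            settled = True
                        elif arch == "migrant":
                            mode = "settled"
                        elif arch == "returner" and not returning:
                            mode = "stopover"
                            roost = cur
                            away_until = ts + timedelta(days=int(rng.integers(1, 3)))
                        elif arch == "returner" and returning:
                            mode = "resident"
                            roost = origin_roost
                else:
                    state = 0  # roosting en route by day
            elif mode == "stopover":
                if away_until is not None and ts >= away_until:
                    mode = "travel"
                    returning = True
                cur = roost if state == 0 else _move(
                    roost[0], roost[1], float(rng.uniform(0, 360)), float(rng.uniform(0.2, 4.0))
                )
            elif mode == "settled":
                cur = (target.lat, target.lon) if target else cur
                state = 0
            elif mode.startswith("crossing"):
                cross_path.pop(0)
                cur = cross_path[0] if cross_path else roost
                state = 1
                if not cross_path or len(cross_path) == 1:
                    mode = "resident"
                    cur = roost
            else:  # resident behaviour around the current roost
                if arch == "crosser" and cross_dest is not None:
                    zvals = {
                        "hours_since_sunset": hss,
                        "wind_speed": wind,
                        "temperature": temp,
                    }
                    eta_c = cb.get("intercept", -math.inf) + sum(
                        cb[k2] * zvals[k2] for k2 in zvals if k2 in cb
                    )
                    if rng.random() < _sigmoid(eta_c):
                        dest = cross_dest if roost == origin_roost else origin_roost
                        # two-hour transit: midpoint over water, then land
                        mid = (
                            (cur[0] + dest[0]) / 2.0,
                            (cur[1] + dest[1]) / 2.0,
                        )
                        cross_path = [cur, mid, dest]
                        roost = dest
                        mode = "crossing"
                        night = _night_of(ts, cur[0], cur[1], solar)
                        crossing_nights.append(night)
                        state = 1
                        cur = cross_path[0]
                        states_out.append("active")
                        pos_rows.append((tag_id, ts, cur[0], cur[1], "active"))
                        continue
                if state == 0:
                    cur = roost
                else:
                    r = min(float(rng.uniform(0.2, 5.0)), 9.0)
                    cur = _move(roost[0], roost[1], float(rng.uniform(0, 360)), r)

            label = "active" if state == 1 else "rest"
            states_out.append(label)
            pos_rows.append((tag_id, ts, cur[0], cur[1], label))

        realised = arch
        if arch == "crosser" and not crossing_nights:
            realised = "resident"
        truth.append(
            TruthLabel(
                tag_id=tag_id,
                archetype=realised,
                drawn_heading_deg=drawn_heading,
                true_crossing_nights=crossing_nights,
                hourly_state=pd.Series(
                    states_out, index=pd.DatetimeIndex(hours, tz="UTC"), name=tag_id
                ),
            )
        )

    positions = pd.DataFrame(pos_rows, columns=["tag_id", "timestamp", "lat", "lon", "state"])
    positions["timestamp"] = pd.DatetimeIndex(positions["timestamp"], tz="UTC")
    return deployments, positions, truth


def _night_of(ts: datetime, lat: float, lon: float, solar: _SolarCache) -> date:
    """Date of the most recent sunset (night label during night hours)."""
    for back in (0, 1):
        d = (ts - timedelta(days=back)).date()
        s = sunset_utc(d, round(lat, 1), round(lon, 1))
        if s <= ts:
            return d
    raise RuntimeError("no recent sunset")  # pragma: no cover


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------


def simulate_detections(
    positions: pd.DataFrame, towers: Sequence[Tower], config: ScenarioConfig
) -> list[Detection]:
    """Turn ground-truth positions into noisy tower detections.

    Detection probability is 1 within ``full_detection_km`` of a tower and
    decays linearly to 0 at ``detection_range_km``.  Signal strength is
    ``s0 - k*ln(d+1)`` plus Gaussian noise whose short-interval variance is
    larger while the bat is in the "active" truth state — the feature that
    makes the downstream activity HMM recoverable.  Each detected bat-hour
    yields a run of pulses per antenna; ``run_length`` is the burst size.
    Occasional sub-threshold noise runs (length <= 3) are also emitted.
    """
    rng = np.random.default_rng([config.seed, 14])
    tlat = np.array([t.lat for t in towers])
    tlon = np.array([t.lon for t in towers])
    tids = [t.tower_id for t in towers]

    lat = positions["lat"].to_numpy()
    lon = positions["lon"].to_numpy()
    # vectorised haversine: positions x towers
    p1 = np.radians(lat)[:, None]
    p2 = np.radians(tlat)[None, :]
    dphi = p2 - p1
    dlmb = np.radians(tlon)[None, :] - np.radians(lon)[:, None]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    dist = 2.0 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))

    rng_km = config.detection_range_km
    full_km = config.full_detection_km
    prob = np.clip((rng_km - dist) / (rng_km - full_km), 0.0, 1.0)

    tags = positions["tag_id"].to_numpy()
    stamps = positions["timestamp"].to_numpy()
    states = positions["state"].to_numpy()

    detections: list[Detection] = []
    in_range = np.argwhere(prob > 0.0)
    draws = rng.random(len(in_range))
    for (row, tcol), u in zip(in_range, draws):
        if u >= prob[row, tcol]:
            continue
        d_km = dist[row, tcol]
        ts = pd.Timestamp(stamps[row]).to_pydatetime()
        sd = config.signal_sd_active if states[row] == "active" else config.signal_sd_rest
        base = config.signal_s0 - config.signal_k * math.log(d_km + 1.0)
        n_ant = 1 + int(rng.random() < 0.5)
        ants = rng.choice(["a1", "a2", "a3"], size=n_ant, replace=False)
        for ant in ants:
            n_pulse = 4 + int(rng.poisson(3.0))
            minutes = np.sort(rng.uniform(0.0, 59.9, n_pulse))
            sig = base + rng.normal(0.0, sd, n_pulse)
            for m, s in zip(minutes, sig):
                detections.append(
                    Detection(
                        tag_id=str(tags[row]),
                        timestamp=ts + timedelta(minutes=float(m)),
                        tower_id=tids[tcol],
                        antenna_id=str(ant),
                        signal_strength=float(s),
                        run_length=n_pulse,
                    )
                )
        if rng.random() < config.noise_run_prob:
            nl = int(rng.integers(1, 4))
            detections.append(
                Detection(
                    tag_id=str(tags[row]),
                    timestamp=ts + timedelta(minutes=float(rng.uniform(0, 59))),
                    tower_id=tids[tcol],
                    antenna_id="a1",
                    signal_strength=float(base + rng.normal(0.0, 10.0)),
                    run_length=nl,
                )
            )
    detections.sort(key=lambda d: (d.tag_id, d.timestamp))
    return detections


def _apply_tag_drops(
    detections: list[Detection],
    deployments: Sequence[Deployment],
    towers: Sequence[Tower],
    config: ScenarioConfig,
) -> list[Detection]:
    """Replace the tail of some tags with a shed-transmitter steady signal.

    A shed tag lies on the ground within range of the last tower and keeps
    pinging with near-constant signal strength until its battery dies; the
    bat's real detections after the drop instant are lost.
    """
    rng = np.random.default_rng([config.seed, 15])
    by_tag: dict[str, list[Detection]] = {}
    for d in detections:
        by_tag.setdefault(d.tag_id, []).append(d)
    out: list[Detection] = []
    for dep in deployments:
        dets = by_tag.get(dep.tag_id, [])
        battery_end = dep.release_time + timedelta(days=dep.tag_life_days)
        tail_days = float(rng.uniform(7.5, 10.0))
        dropped = bool(rng.random() < config.tag_drop_prob)
        drop_time = battery_end - timedelta(days=tail_days)
        if not dets or not dropped or drop_time <= dep.release_time + timedelta(days=4):
            out.extend(dets)
            continue
        kept = [d for d in dets if d.timestamp < drop_time]
        if not kept:
            out.extend(dets)
            continue
        last = kept[-1]
        level = float(rng.normal(45.0, 3.0))
        t0 = drop_time.replace(minute=0, second=0, microsecond=0) + timedelta(hours=1)
        out.extend(kept)
        h = 0
        while t0 + timedelta(hours=h) < battery_end:
            out.append(
                Detection(
                    tag_id=dep.tag_id,
                    timestamp=t0 + timedelta(hours=h),
                    tower_id=last.tower_id,
                    antenna_id=last.antenna_id,
                    signal_strength=level + float(rng.normal(0.0, 0.05)),
                    run_length=6,
                )
            )
            h += 2
    out.sort(key=lambda d: (d.tag_id, d.timestamp))
    return out


def simulate_scenario(config: ScenarioConfig) -> dict:
    """Run the full generator: towers, weather, bats, detections, truth.

    Returns a dict with keys ``towers, weather, deployments, positions,
    truth, detections``.
    """
    towers = make_towers(config)
    weather = simulate_weather(config)
    deployments, positions, truth = simulate_bats(config, towers, weather)
    detections = simulate_detections(positions, towers, config)
    detections = _apply_tag_drops(detections, deployments, towers, config)
    return {
        "towers": towers,
        "weather": weather,
        "deployments": deployments,
        "positions": positions,
        "truth": truth,
        "detections": detections,
    }


# ---------------------------------------------------------------------------
# Direct simulation harnesses for the two statistical recovery studies
# ---------------------------------------------------------------------------


def simulate_hmm_series(
    hmm_truth: Mapping,
    n_hours: int,
    seed: int,
    start: datetime | None = None,
    lat: float = 37.3,
    lon: float = -75.9,
) -> tuple[pd.DatetimeIndex, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate an hourly activity series directly from two-state truth.

    States follow the covariate-transition chain (logit switch probability in
    sine/cosine of hours-since-sunset); emissions are state-conditional
    Gaussians clipped at zero (the observable is a standard deviation).

    Returns ``(hours, values, states, hss)`` with states coded 0=rest,
    1=active.
    """
    rng = np.random.default_rng(seed)
    if start is None:
        start = datetime(2021, 9, 1, 0, 0, tzinfo=timezone.utc)
    hours = pd.date_range(start, periods=n_hours, freq="h", tz="UTC")
    solar = _SolarCache()
    hss = np.array([solar.hss(ts.to_pydatetime(), lat, lon) for ts in hours])
    ang = 2.0 * np.pi * (hss % 24.0) / 24.0
    Z = np.column_stack([np.ones(n_hours), np.sin(ang), np.cos(ang)])

    c = np.vstack([hmm_truth["trans_from_rest"], hmm_truth["trans_from_active"]])
    mu = np.array([hmm_truth["mu_rest"], hmm_truth["mu_active"]])
    sd = np.array([hmm_truth["sd_rest"], hmm_truth["sd_active"]])

    states = np.empty(n_hours, dtype=int)
    states[0] = rng.integers(0, 2)
    for t in range(1, n_hours):
        p_active = 1.0 / (1.0 + np.exp(-Z[t] @ c[states[t - 1]]))
        states[t] = int(rng.random() < p_active)
    values = np.clip(rng.normal(mu[states], sd[states]), 0.0, None)
    return hours, values, states, hss


def simulate_crossing_hours(
    weather: pd.DataFrame,
    deployments: Sequence[Deployment],
    beta: Mapping[str, float],
    seed: int,
    horizon_days: float = 40.0,
) -> list[tuple[str, datetime]]:
    """Draw used (crossing) hours from the true logistic propensity model.

    For every whole hour in each tag's ``[release, release + horizon_days]``
    window, a crossing occurs with probability
    ``logistic(beta . covariates(hour))``; covariates are looked up from the
    weather table and hours-since-sunset at the tag's release location.
    Returns ``(tag_id, hour)`` pairs — the "used" points for the
    use-availability stage, against which parameter recovery is measured.
    """
    rng = np.random.default_rng(seed)
    wx = weather.set_index("timestamp")
    solar = _SolarCache()
    used: list[tuple[str, datetime]] = []
    for dep in deployments:
        start = pd.Timestamp(dep.release_time).ceil("h")
        end = pd.Timestamp(dep.release_time) + pd.Timedelta(days=horizon_days)
        hours = pd.date_range(start, end, freq="h", inclusive="left")
        hours = hours[hours.isin(wx.index)]
        hss = np.array(
            [solar.hss(ts.to_pydatetime(), dep.release_lat, dep.release_lon) for ts in hours]
        )
        covs = {
            "hours_since_sunset": hss,
            "wind_speed": wx["wind_speed"].loc[hours].to_numpy(),
            "temperature": wx["temperature"].loc[hours].to_numpy(),
            "precipitation": wx["precipitation"].loc[hours].to_numpy(),
            "visibility": wx["visibility"].loc[hours].to_numpy(),
            "pressure": wx["pressure"].loc[hours].to_numpy(),
        }
        eta = np.full(len(hours), beta.get("intercept", 0.0))
        for name, coef in beta.items():
            if name == "intercept":
                continue
            eta += coef * covs[name]
        p = 1.0 / (1.0 + np.exp(-eta))
        hits = rng.random(len(hours)) < p
        used.extend((dep.tag_id, ts.to_pydatetime()) for ts in hours[hits])
    return used


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------


def write_truth(truth: Sequence[TruthLabel], path) -> None:
    rows = []
    for t in truth:
        rows.append(
            {
                "tag_id": t.tag_id,
                "archetype": t.archetype,
                "drawn_heading_deg": t.drawn_heading_deg,
                "crossing_nights": ";".join(d.isoformat() for d in t.true_crossing_nights),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
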