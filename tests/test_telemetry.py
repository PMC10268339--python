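"""Geodesy, solar time, CSV round-trips, and the cleaning filters."""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, strategies as st

from batmove.telemetry import (
    Tower,
    Track,
    cyclical_hour,
    filter_implausible,
    filter_run_length,
    haversine_km,
    hours_since_sunset,
    initial_bearing_deg,
    night_id,
    read_deployments,
    read_detections,
    read_towers,
    sunset_utc,
    trim_tag_drop,
    write_deployments,
    write_detections,
    write_towers,
)

from conftest import KM_LAT, mk_dep, mk_det, utc

coord = st.floats(min_value=-80, max_value=80, allow_nan=False)
lon_st = st.floats(min_value=-179, max_value=179, allow_nan=False)


# ---------------------------------------------------------------------------
# Geodesy
# ---------------------------------------------------------------------------


class TestHaversine:
    def test_identity_and_equator_degree(self):
        assert haversine_km(0, 0, 0, 0) == 0.0
        # one degree of arc on the R=6371 sphere: 2*pi*R/360
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.1949, abs=1e-3)

    @given(coord, lon_st, coord, lon_st)
    def test_symmetry(self, lat1, lon1, lat2, lon2):
        assert haversine_km(lat1, lon1, lat2, lon2) == pytest.approx(
            haversine_km(lat2, lon2, lat1, lon1), abs=1e-9
        )

    @given(coord, lon_st, coord, lon_st, coord, lon_st)
    def test_triangle_inequality(self, la1, lo1, la2, lo2, la3, lo3):
        ab = haversine_km(la1, lo1, la2, lo2)
        bc = haversine_km(la2, lo2, la3, lo3)
        ac = haversine_km(la1, lo1, la3, lo3)
        assert ac <= ab + bc + 1e-9

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            haversine_km(float("nan"), 0, 0, 0)


def _bearing_oracle(lat1, lon1, lat2, lon2):
    """Independent bearing via 3-D unit vectors and a local ENU basis."""
    def unit(lat, lon):
        la, lo = math.radians(lat), math.radians(lon)
        return np.array(
            [math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo), math.sin(la)]
        )

    n1, n2 = unit(lat1, lon1), unit(lat2, lon2)
    t = n2 - n1 * np.dot(n1, n2)  # tangent of the great circle at point 1
    t /= np.linalg.norm(t)
    east = np.cross([0.0, 0.0, 1.0], n1)
    east /= np.linalg.norm(east)
    north = np.cross(n1, east)
    return math.degrees(math.atan2(np.dot(t, east), np.dot(t, north))) % 360.0


class TestBearing:
    @pytest.mark.parametrize(
        "p1,p2,expect",
        [((0, 0), (0, 1), 90.0), ((0, 0), (1, 0), 0.0), ((0, 0), (-1, 0), 180.0)],
    )
    def test_cardinal_directions(self, p1, p2, expect):
        assert initial_bearing_deg(*p1, *p2) == pytest.approx(expect, abs=1e-9)

    def test_matches_vector_oracle_mid_atlantic(self):
        got = initial_bearing_deg(38.0, -75.5, 37.0, -76.5)
        assert got == pytest.approx(_bearing_oracle(38.0, -75.5, 37.0, -76.5), abs=1e-6)

    @given(coord, lon_st, coord, lon_st)
    def test_matches_vector_oracle_random(self, lat1, lon1, lat2, lon2):
        if abs(lat1 - lat2) < 1e-6 and abs(lon1 - lon2) < 1e-6:
            return
        got = initial_bearing_deg(lat1, lon1, lat2, lon2)
        want = _bearing_oracle(lat1, lon1, lat2, lon2)
        assert min(abs(got - want), 360 - abs(got - want)) < 1e-5

    def test_coincident_points_error(self):
        with pytest.raises(ValueError):
            initial_bearing_deg(37.0, -76.0, 37.0, -76.0)


# ---------------------------------------------------------------------------
# Solar time
# ---------------------------------------------------------------------------


def _spencer_sunset(d: date, lat: float, lon: float) -> datetime:
    """Independent sunset oracle from the Spencer Fourier-series expansion."""
    doy = d.timetuple().tm_yday
    g = 2 * math.pi / 365 * (doy - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    phi = math.radians(lat)
    cos_ha = math.cos(math.radians(90.833)) / (math.cos(phi) * math.cos(decl)) - math.tan(
        phi
    ) * math.tan(decl)
    ha = math.degrees(math.acos(cos_ha))
    minutes = 720 - 4 * (lon - ha) - eqtime
    return datetime(d.year, d.month, d.day, tzinfo=timezone.utc) + timedelta(minutes=minutes)


class TestSolar:
    @pytest.mark.parametrize(
        "d,lat,lon",
        [
            (date(2019, 9, 10), 37.0, -76.0),
            (date(2021, 8, 15), 39.0, -74.9),
            (date(2021, 10, 15), 38.0, -75.5),
            (date(2021, 6, 21), 45.0, 7.0),
        ],
    )
    def test_sunset_matches_spencer_oracle_within_two_minutes(self, d, lat, lon):
        got = sunset_utc(d, lat, lon)
        want = _spencer_sunset(d, lat, lon)
        assert abs((got - want).total_seconds()) < 120

    def test_hours_since_sunset_zero_and_linear(self):
        s = sunset_utc(date(2021, 9, 1), 37.3, -76.0)
        assert hours_since_sunset(s, 37.3, -76.0) == pytest.approx(0.0, abs=1e-9)
        assert hours_since_sunset(s + timedelta(hours=3), 37.3, -76.0) == pytest.approx(3.0)

    def test_polar_night_raises(self):
        with pytest.raises(ValueError):
            sunset_utc(date(2021, 12, 21), 85.0, 0.0)

    def test_night_id_constant_over_night_and_increments_at_sunrise(self):
        lat, lon = 37.3, -76.0
        s = sunset_utc(date(2021, 9, 1), lat, lon)
        ids = {
            night_id(s + timedelta(minutes=m), lat, lon)
            for m in range(1, 12 * 60, 37)
            if hours_since_sunset(s + timedelta(minutes=m), lat, lon) < 10.5
        }
        assert ids == {date(2021, 9, 1)}
        next_noon = utc("2021-09-02 16:00")  # local late morning, after sunrise
        assert night_id(next_noon, lat, lon) == date(2021, 9, 2)


class TestCyclicalHour:
    @pytest.mark.parametrize("h,expect", [(0.0, (0, 1)), (6.0, (1, 0)), (12.0, (0, -1))])
    def test_quarter_points(self, h, expect):
        s, c = cyclical_hour(h)
        assert (s, c) == pytest.approx(expect, abs=1e-12)

    @given(st.floats(min_value=0, max_value=23.999))
    def test_unit_circle(self, h):
        s, c = cyclical_hour(h)
        assert s * s + c * c == pytest.approx(1.0)
        assert -1 <= s <= 1 and -1 <= c <= 1

    @pytest.mark.parametrize("h", [-0.1, 24.0, 30.0])
    def test_rejects_out_of_range(self, h):
        with pytest.raises(ValueError):
            cyclical_hour(h)


# ---------------------------------------------------------------------------
# Cleaning filters
# ---------------------------------------------------------------------------


class TestRunLengthFilter:
    def test_keeps_only_runs_longer_than_three(self):
        dets = [mk_det(run=r) for r in (2, 3, 4)]
        kept = filter_run_length(dets)
        assert [d.run_length for d in kept] == [4]

    def test_empty_and_all_pass(self):
        assert filter_run_length([]) == []
        dets = [mk_det(run=10) for _ in range(5)]
        assert filter_run_length(dets) == dets

    @given(st.lists(st.integers(min_value=1, max_value=12), max_size=30))
    def test_idempotent_and_subsequence(self, runs):
        dets = [mk_det(run=r) for r in runs]
        once = filter_run_length(dets)
        assert filter_run_length(once) == once
        it = iter(dets)
        assert all(d in it for d in once)  # order-preserving subsequence


def _track_with_towers(offsets_km, release=("t1", 37.0, -76.0)):
    tag, lat, lon = release
    towers = [Tower(f"tw{i}", lat + km * KM_LAT, lon, {}) for i, km in enumerate(offsets_km)]
    dets = [
        mk_det(tag=tag, ts=utc("2021-09-01 02:00") + timedelta(hours=i), tower=f"tw{i}")
        for i in range(len(offsets_km))
    ]
    dep = mk_dep(tag=tag, lat=lat, lon=lon)
    return Track(tag, dets, dep), towers


class TestImplausibleFilter:
    def test_removes_lone_distant_detection(self):
        track, towers = _track_with_towers([5, 2500, 40, 60])
        out = filter_implausible(track, towers)
        assert [d.tower_id for d in out.detections] == ["tw0", "tw2", "tw3"]

    def test_keeps_everything_nearby(self):
        track, towers = _track_with_towers([5, 10, 50])
        out = filter_implausible(track, towers)
        assert out.detections == track.detections

    def test_strictly_beyond_threshold_only(self):
        track, towers = _track_with_towers([999.0])
        assert len(filter_implausible(track, towers).detections) == 1
        track2, towers2 = _track_with_towers([1000.5])
        assert len(filter_implausible(track2, towers2).detections) == 0

    def test_chained_detections_anchor_each_other(self):
        # 900 km and 1700 km are each within 1000 km of a neighbour
        track, towers = _track_with_towers([5, 900, 1700])
        out = filter_implausible(track, towers)
        assert len(out.detections) == 3

    def test_unknown_tower_raises_with_id(self):
        track, _ = _track_with_towers([5])
        with pytest.raises(KeyError, match="tw0"):
            filter_implausible(track, [])

    def test_idempotent(self):
        track, towers = _track_with_towers([5, 2500, 40])
        once = filter_implausible(track, towers)
        twice = filter_implausible(once, towers)
        assert twice.detections == once.detections


class TestTagDropTrim:
    def _steady_tail_track(self, days, sd, n_head=50):
        rng = np.random.default_rng(0)
        t0 = utc("2021-09-01 02:00")
        dets = [
            mk_det(ts=t0 + timedelta(hours=i), tower="tw1", antenna="a1",
                   signal=50 + 10 * rng.standard_normal())
            for i in range(n_head)
        ]
        tail_start = t0 + timedelta(hours=n_head)
        for i in range(int(days * 24)):
            dets.append(
                mk_det(ts=tail_start + timedelta(hours=i), tower="tw2", antenna="a1",
                       signal=45 + sd * rng.standard_normal())
            )
        return Track("t1", dets, mk_dep()), n_head

    def test_removes_long_steady_terminal_segment(self):
        track, n_head = self._steady_tail_track(days=8, sd=0.01)
        out = trim_tag_drop(track)
        assert len(out.detections) == n_head

    def test_keeps_varying_terminal_segment(self):
        track, _ = self._steady_tail_track(days=8, sd=20.0)
        assert len(trim_tag_drop(track).detections) == len(track.detections)

    def test_keeps_short_steady_segment(self):
        track, _ = self._steady_tail_track(days=3, sd=0.01)
        assert len(trim_tag_drop(track).detections) == len(track.detections)

    def test_idempotent(self):
        track, _ = self._steady_tail_track(days=8, sd=0.01)
        once = trim_tag_drop(track)
        assert trim_tag_drop(once).detections == once.detections


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


class TestCsvRoundTrips:
    def test_detections_round_trip(self, tmp_path):
        dets = [
            mk_det(ts="2019-09-10 23:15", signal=-87.25, run=7),
            mk_det(tag="t2", ts="2019-09-11 01:00", tower="tw9"),
            mk_det(tag="t3", ts="2019-09-12 03:30", antenna="a2"),
        ]
        p = tmp_path / "d.csv"
        write_detections(dets, p)
        assert read_detections(p) == dets

    def test_detection_timestamp_parsed_utc(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "tag_id,timestamp,tower_id,antenna_id,signal_strength,run_length\n"
            "t1,2019-09-10T23:15:00Z,tw1,a1,-80,5\n"
        )
        (det,) = read_detections(p)
        assert det.timestamp == utc("2019-09-10 23:15")

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("tag_id,timestamp,tower_id,antenna_id,run_length\nt1,2019-09-10T23:15:00Z,tw1,a1,5\n")
        with pytest.raises(ValueError, match="signal_strength"):
            read_detections(p)

    def test_bad_timestamp_names_row(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "tag_id,timestamp,tower_id,antenna_id,signal_strength,run_length\n"
            "t1,2019-09-10T23:15:00Z,tw1,a1,-80,5\n"
            "t1,not-a-time,tw1,a1,-80,5\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_detections(p)

    def test_towers_round_trip_with_sides(self, tmp_path):
        towers = [
            Tower("tw1", 37.1, -76.0, {"chesapeake": "east"}),
            Tower("tw2", 38.6, -75.3, {"delaware": "west"}),
            Tower("tw3", 36.5, -77.5, {}),
        ]
        p = tmp_path / "t.csv"
        write_towers(towers, p)
        got = sorted(read_towers(p), key=lambda t: t.tower_id)
        assert got == towers

    def test_deployments_round_trip(self, tmp_path):
        deps = [mk_dep(), mk_dep(tag="t2", lat=38.0, life=22.5)]
        p = tmp_path / "dep.csv"
        write_deployments(deps, p)
        assert read_deployments(p) == deps
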