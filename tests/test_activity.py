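"""Activity series construction and the covariate-transition HMM."""

from __future__ import annotations

import itertools
import math
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from batmove.activity import (
    HourlyActivitySeries,
    build_activity_series,
    decode_states,
    fit_hmm,
    forward_loglik,
    select_residents,
    state_condition_trends,
    transition_matrices,
)
from batmove.synth import _default_hmm_truth, simulate_hmm_series
from batmove.telemetry import Tower, Track

from conftest import mk_dep, mk_det, utc


# ---------------------------------------------------------------------------
# Series construction
# ---------------------------------------------------------------------------

LOCAL = Tower("tw1", 37.31, -76.0, {})


def _series_track(per_hour: dict[str, list[tuple[int, str, float]]]) -> Track:
    """Build a track from {hour_iso: [(minute, antenna, signal), ...]}."""
    dets = []
    for hour, pulses in per_hour.items():
        t0 = utc(hour)
        for minute, ant, sig in pulses:
            dets.append(
                mk_det(ts=t0 + timedelta(minutes=minute), tower="tw1", antenna=ant, signal=sig)
            )
    return Track("t1", dets, mk_dep(lat=37.3, lon=-76.0))


class TestSeriesConstruction:
    def test_constant_signal_hour_scores_zero(self):
        track = _series_track(
            {
                "2021-09-02 01:00": [(0, "a1", 50.0), (10, "a1", 50.0), (20, "a1", 50.0)],
                "2021-09-02 02:00": [(0, "a1", 40.0), (30, "a1", 60.0)],
            }
        )
        series = build_activity_series(track, [LOCAL])
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_antenna_average(self):
        # per antenna the scaled hourly SDs differ; the series is their mean
        track = _series_track(
            {
                "2021-09-02 01:00": [
                    (0, "a1", 50.0), (10, "a1", 54.0),
                    (0, "a2", 10.0), (10, "a2", 18.0),
                ],
                "2021-09-02 02:00": [
                    (0, "a1", 40.0), (10, "a1", 60.0),
                    (0, "a2", 12.0), (10, "a2", 13.0),
                ],
            }
        )
        series = build_activity_series(track, [LOCAL])
        df = pd.DataFrame(
            {
                "hour": ["h1", "h1", "h2", "h2"],
                "ant": ["a1", "a2", "a1", "a2"],
                "sig": [[50.0, 54.0], [10.0, 18.0], [40.0, 60.0], [12.0, 13.0]],
            }
        )
        sd1 = np.std([50, 54, 40, 60], ddof=1)
        sd2 = np.std([10, 18, 12, 13], ddof=1)
        h1 = np.mean([np.std([50, 54], ddof=1) / sd1, np.std([10, 18], ddof=1) / sd2])
        h2 = np.mean([np.std([40, 60], ddof=1) / sd1, np.std([12, 13], ddof=1) / sd2])
        assert series.values == pytest.approx([h1, h2])

    def test_single_detection_hours_are_missing_not_zero(self):
        track = _series_track(
            {
                "2021-09-02 01:00": [(0, "a1", 50.0)],  # one pulse: no SD
                "2021-09-02 02:00": [(0, "a1", 40.0), (30, "a1", 60.0)],
                "2021-09-02 03:00": [(0, "a1", 42.0), (30, "a1", 58.0)],
            }
        )
        series = build_activity_series(track, [LOCAL])
        assert len(series) == 2
        assert series.hours[0] == pd.Timestamp("2021-09-02 02:00", tz="UTC")

    def test_gain_invariance(self):
        base = {
            "2021-09-02 01:00": [(0, "a1", 50.0), (10, "a1", 54.0), (0, "a2", 10.0), (10, "a2", 18.0)],
            "2021-09-02 02:00": [(0, "a1", 40.0), (10, "a1", 60.0), (0, "a2", 12.0), (10, "a2", 13.0)],
        }
        series1 = build_activity_series(_series_track(base), [LOCAL])
        scaled = {
            h: [(m, a, s * (7.5 if a == "a2" else 1.0)) for m, a, s in pulses]
            for h, pulses in base.items()
        }
        series2 = build_activity_series(_series_track(scaled), [LOCAL])
        assert series1.values == pytest.approx(series2.values)

    def test_segment_split_on_long_gap(self):
        track = _series_track(
            {
                "2021-09-02 01:00": [(0, "a1", 40.0), (30, "a1", 60.0)],
                "2021-09-02 03:00": [(0, "a1", 40.0), (30, "a1", 60.0)],
                "2021-09-02 23:00": [(0, "a1", 40.0), (30, "a1", 60.0)],
            }
        )
        series = build_activity_series(track, [LOCAL])
        assert list(series.segment_id) == [0, 0, 1]


class TestResidentSelection:
    def _resident_track(self, dates, tag="t1"):
        dets = []
        for d in dates:
            for hh in (1, 3):
                dets.append(mk_det(tag=tag, ts=utc(f"{d} 0{hh}:00"), tower="tw1"))
        return Track(tag, dets, mk_dep(tag=tag, lat=37.3, lon=-76.0))

    def test_long_consistent_resident_kept(self):
        dates = [f"2021-09-{d:02d}" for d in range(1, 27)]
        track = self._resident_track(dates)
        assert select_residents([track], [LOCAL]) == [track]

    def test_three_day_gap_dropped(self):
        dates = [f"2021-09-{d:02d}" for d in range(1, 27) if d not in (10, 11, 12)]
        track = self._resident_track(dates)
        assert select_residents([track], [LOCAL]) == []

    def test_two_day_gap_kept(self):
        dates = [f"2021-09-{d:02d}" for d in range(1, 27) if d not in (10, 11)]
        track = self._resident_track(dates)
        assert select_residents([track], [LOCAL]) == [track]

    def test_short_resident_dropped(self):
        dates = [f"2021-09-{d:02d}" for d in range(1, 16)]
        track = self._resident_track(dates)
        assert select_residents([track], [LOCAL]) == []

    def test_exactly_twenty_days_dropped_strict(self):
        # release 2021-08-31 -> last detection 2021-09-20 is exactly 20 days
        dates = [f"2021-09-{d:02d}" for d in range(1, 21)]
        track = self._resident_track(dates)
        assert select_residents([track], [LOCAL], min_days=20) == []
        dates21 = [f"2021-09-{d:02d}" for d in range(1, 22)]
        assert select_residents([self._resident_track(dates21)], [LOCAL]) != []


# ---------------------------------------------------------------------------
# HMM: oracle equivalence and EM behaviour
# ---------------------------------------------------------------------------


def _toy_series(n=8, seed=0):
    truth = _default_hmm_truth()
    hours, values, states, hss = simulate_hmm_series(truth, n, seed=seed)
    ang = 2 * np.pi * (hss % 24) / 24
    cov = pd.DataFrame(
        {
            "hours_since_sunset": hss,
            "sin_hss": np.sin(ang),
            "cos_hss": np.cos(ang),
            "night": hss < 11,
            "date_ordinal": [h.toordinal() for h in hours],
            "temperature": 15.0,
            "wind_speed": 3.0,
        },
        index=hours,
    )
    series = HourlyActivitySeries("toy", hours, values, cov, np.zeros(n, int))
    return series, states


def _enumerate_loglik(params, series):
    """Brute-force marginal likelihood over all 2^T state paths."""
    mu, sd, pi, coef = params
    v = series.values
    Z = np.column_stack(
        [np.ones(len(series)), series.covariates["sin_hss"], series.covariates["cos_hss"]]
    )
    T = len(v)
    best_path, best_lp, total = None, -np.inf, -np.inf
    for path in itertools.product((0, 1), repeat=T):
        lp = math.log(pi[path[0]])
        for t in range(T):
            lp += -0.5 * ((v[t] - mu[path[t]]) / sd[path[t]]) ** 2 - math.log(
                sd[path[t]] * math.sqrt(2 * math.pi)
            )
            if t > 0:
                p_active = 1.0 / (1.0 + math.exp(-(Z[t] @ coef[path[t - 1]])))
                lp += math.log(p_active if path[t] == 1 else 1.0 - p_active)
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return total, np.array(best_path)


PARAMS = (
    np.array([0.25, 0.9]),
    np.array([0.12, 0.3]),
    np.array([0.45, 0.55]),
    np.array([[-1.0, 2.5, 2.0], [1.2, 2.5, 2.0]]),
)


class TestOracleEquivalence:
    @pytest.mark.parametrize("t_len,seed", [(8, 0), (8, 3), (10, 1)])
    def test_forward_matches_enumeration(self, t_len, seed):
        series, _ = _toy_series(n=t_len, seed=seed)
        want, _ = _enumerate_loglik(PARAMS, series)
        got = forward_loglik(PARAMS, series)
        assert abs(got - want) < 1e-8

    @pytest.mark.parametrize("t_len,seed", [(8, 0), (8, 5), (10, 2)])
    def test_viterbi_matches_enumeration(self, t_len, seed):
        series, _ = _toy_series(n=t_len, seed=seed)
        _, want = _enumerate_loglik(PARAMS, series)
        got = decode_states(PARAMS, series)
        assert (got == want).all()


class TestTransitionMatrices:
    def test_rows_sum_to_one_for_arbitrary_covariates(self):
        rng = np.random.default_rng(0)
        Z = np.column_stack([np.ones(200), rng.normal(0, 5, 200), rng.normal(0, 5, 200)])
        coef = rng.normal(0, 4, (2, 3))
        A = transition_matrices(coef, Z)
        assert A.shape == (200, 2, 2)
        assert np.allclose(A.sum(axis=2), 1.0)
        assert (A >= 0).all()


@pytest.fixture(scope="module")
def fitted():
    series, states = _toy_series(n=600, seed=21)
    fit = fit_hmm(series, restarts=4, seed=2)
    return fit, series, states


class TestEmFitting:
    def test_em_loglik_non_decreasing(self, fitted):
        fit, _, _ = fitted
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-9).all()

    def test_active_state_has_larger_mean(self, fitted):
        fit, _, _ = fitted
        assert fit.state_means[1] > fit.state_means[0]
        assert (fit.state_sds > 0).all()

    def test_recovers_truth_roughly(self, fitted):
        fit, series, states = fitted
        truth = _default_hmm_truth()
        assert fit.state_means[0] == pytest.approx(truth["mu_rest"], rel=0.15)
        assert fit.state_means[1] == pytest.approx(truth["mu_active"], rel=0.15)
        acc = (fit.decoded_states == states).mean()
        assert acc >= 0.85

    def test_label_swap_symmetry(self, fitted):
        fit, series, _ = fitted
        mu, sd, pi, coef = fit.state_means, fit.state_sds, fit.init_prob, fit.trans_coef
        swapped = (
            mu[::-1].copy(),
            sd[::-1].copy(),
            pi[::-1].copy(),
            np.vstack([-coef[1], -coef[0]]),
        )
        same = forward_loglik((mu, sd, pi, coef), series)
        flipped = forward_loglik(swapped, series)
        assert flipped == pytest.approx(same, abs=1e-8)
        assert (decode_states(swapped, series) == 1 - decode_states(fit, series)).all()

    def test_too_short_series_rejected(self):
        series, _ = _toy_series(n=20, seed=1)
        with pytest.raises(ValueError):
            fit_hmm(series)

    def test_dominant_emission_limit_is_nearest_mean(self):
        n = 60
        rng = np.random.default_rng(3)
        hours = pd.date_range("2021-09-01", periods=n, freq="h", tz="UTC")
        values = np.where(rng.random(n) < 0.5, 0.0, 10.0) + rng.normal(0, 0.01, n)
        cov = pd.DataFrame(
            {"sin_hss": 0.0, "cos_hss": 1.0, "hours_since_sunset": 1.0,
             "night": True, "date_ordinal": 1, "temperature": 15.0, "wind_speed": 3.0},
            index=hours,
        )
        series = HourlyActivitySeries("x", hours, values, cov, np.zeros(n, int))
        params = (
            np.array([0.0, 10.0]),
            np.array([1.0, 1.0]),
            np.array([0.5, 0.5]),
            np.zeros((2, 3)),
        )
        got = decode_states(params, series)
        assert (got == (values > 5.0)).all()


class TestTrends:
    def test_separating_temperature_has_positive_slope(self):
        n = 120
        hours = pd.date_range("2021-09-01", periods=n, freq="h", tz="UTC")
        rng = np.random.default_rng(4)
        temp = rng.uniform(5, 25, n)
        state = (temp + rng.normal(0, 2.0, n) > 15).astype(int)
        cov = pd.DataFrame(
            {"temperature": temp, "wind_speed": 3.0, "hours_since_sunset": 2.0,
             "night": True, "date_ordinal": 738000, "sin_hss": 0.0, "cos_hss": 1.0},
            index=hours,
        )
        trends = state_condition_trends(state, cov, variables=("temperature",))
        assert not trends["temperature"].degenerate
        assert trends["temperature"].slope > 0

    def test_night_filter_drops_day_hours(self):
        n = 50
        hours = pd.date_range("2021-09-01", periods=n, freq="h", tz="UTC")
        night = np.arange(n) % 2 == 0
        state = np.arange(n) % 2  # active only in day hours
        cov = pd.DataFrame(
            {"temperature": 15.0, "wind_speed": 3.0, "hours_since_sunset": 2.0,
             "night": night, "date_ordinal": 738000, "sin_hss": 0.0, "cos_hss": 1.0},
            index=hours,
        )
        trends = state_condition_trends(state, cov, variables=("temperature",))
        # every night hour is rest: the fit is degenerate by construction
        assert trends["temperature"].degenerate

    def test_single_state_flagged(self):
        n = 30
        hours = pd.date_range("2021-09-01", periods=n, freq="h", tz="UTC")
        cov = pd.DataFrame(
            {"temperature": 15.0, "wind_speed": 3.0, "hours_since_sunset": 2.0,
             "night": True, "date_ordinal": 738000, "sin_hss": 0.0, "cos_hss": 1.0},
            index=hours,
        )
        trends = state_condition_trends(np.ones(n, int), cov)
        assert all(t.degenerate for t in trends.values())
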