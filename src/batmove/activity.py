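"""Hourly activity metric and covariate-transition hidden Markov models.

A tag on a roosting bat returns a steady signal; a flying bat's signal
fluctuates as the transmitter's range and antenna aspect change.  The
hour-by-hour standard deviation of scaled signal strength is therefore an
activity index for bats in long site residency: per tower antenna, signals
are divided by that antenna's overall standard deviation (making the index
dimensionless and gain-invariant), binned by clock hour, the within-hour SD
taken per antenna, and antenna values averaged.

The index is modelled with a two-state (rest / active) Gaussian HMM whose
transition probabilities vary by hour: the logit of the switch probability
is linear in the sine and cosine of hours-since-sunset, capturing the
diel arousal cycle.  Models are fit per bat by EM (forward-backward with
per-hour transition matrices; weighted Gaussian and weighted-logistic
M-steps), decoded with the Viterbi algorithm, and the decoded night-hour
states are regressed against date, hours-since-sunset, wind speed and
temperature to describe when residents rest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .telemetry import (
    Tower,
    Track,
    cyclical_hour,
    haversine_km,
    hours_since_sunset,
    is_night,
)
from .behavior import classify_residency

logger = logging.getLogger(__name__)

__all__ = [
    "HourlyActivitySeries",
    "HmmFit",
    "select_residents",
    "build_activity_series",
    "fit_hmm",
    "forward_loglik",
    "decode_states",
    "transition_matrices",
    "state_condition_trends",
    "TrendFit",
]

STATE_REST = 0
STATE_ACTIVE = 1

#: Observation gaps longer than this split a series into independent segments.
SEGMENT_GAP_HOURS = 6


# ---------------------------------------------------------------------------
# Series construction
# ---------------------------------------------------------------------------


@dataclass
class HourlyActivitySeries:
    """Hourly SD of scaled signal strength with per-hour covariates.

    ``covariates`` carries ``sin_hss, cos_hss, hours_since_sunset,
    temperature, wind_speed, night, date_ordinal`` aligned with ``hours``;
    ``segment_id`` labels contiguity blocks (gaps > 6 h split segments).
    """

    tag_id: str
    hours: pd.DatetimeIndex
    values: np.ndarray
    covariates: pd.DataFrame
    segment_id: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def select_residents(
    tracks: Iterable[Track],
    towers: Sequence[Tower],
    min_days: int = 20,
    max_gap_days: int = 2,
) -> list[Track]:
    """Keep bats in long, consistent site residency.

    A track is retained when its minimum residency time exceeds
    ``min_days`` and its local detection dates never skip more than
    ``max_gap_days`` consecutive days without a detection.
    """
    kept = []
    tower_ix = {t.tower_id: t for t in towers}
    for track in tracks:
        resident, days = classify_residency(track, towers)
        if not resident or days is None or days <= min_days:
            continue
        dep = track.deployment
        local_dates = sorted(
            {
                d.timestamp.astimezone(timezone.utc).date()
                for d in track.detections
                if d.tower_id in tower_ix
                and haversine_km(
                    tower_ix[d.tower_id].lat,
                    tower_ix[d.tower_id].lon,
                    dep.release_lat,
                    dep.release_lon,
                )
                < 12.0
            }
        )
        gaps_ok = all(
            (b - a).days - 1 <= max_gap_days for a, b in zip(local_dates, local_dates[1:])
        )
        if gaps_ok:
            kept.append(track)
    return kept


def build_activity_series(
    track: Track,
    towers: Sequence[Tower],
    weather: pd.DataFrame | None = None,
) -> HourlyActivitySeries:
    """Hourly activity index for one resident bat at its main tower.

    Uses the local tower with the most detections.  Per antenna, signals
    are scaled by that antenna's overall SD (antennas with zero SD are
    excluded with a warning); the within-hour SD of scaled signal is taken
    per antenna for hours with at least two detections on that antenna, and
    antenna values are averaged per hour.  Hours observed on no antenna are
    missing — not zero, which would mimic rest.
    """
    tower_ix = {t.tower_id: t for t in towers}
    dep = track.deployment
    local = [
        d
        for d in track.detections
        if d.tower_id in tower_ix
        and haversine_km(
            tower_ix[d.tower_id].lat,
            tower_ix[d.tower_id].lon,
            dep.release_lat,
            dep.release_lon,
        )
        < 12.0
    ]
    if len(local) < 2:
        raise ValueError(f"build_activity_series: track {track.tag_id} has < 2 local detections")
    df = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex([d.timestamp for d in local], tz="UTC"),
            "tower_id": [d.tower_id for d in local],
            "antenna_id": [d.antenna_id for d in local],
            "signal": [d.signal_strength for d in local],
        }
    )
    main_tower = df["tower_id"].value_counts().idxmax()
    df = df[df["tower_id"] == main_tower].copy()
    tower = tower_ix[main_tower]

    # per-antenna scaling by the antenna's overall SD
    pieces = []
    for ant, sub in df.groupby("antenna_id"):
        sd = float(sub["signal"].std(ddof=1)) if len(sub) > 1 else 0.0
        if not sd > 0.0:
            logger.warning(
                "antenna %s/%s has zero signal SD; excluded", main_tower, ant
            )
            continue
        s = sub.copy()
        s["scaled"] = s["signal"] / sd
        pieces.append(s)
    if not pieces:
        raise ValueError("build_activity_series: no antenna with positive signal SD")
    df = pd.concat(pieces)
    df["hour"] = df["timestamp"].dt.floor("h")

    # per antenna-hour SD of scaled signal (needs >= 2 detections), then
    # average across antennas observed that hour
    g = df.groupby(["hour", "antenna_id"])["scaled"]
    per_ant = g.agg(["count", lambda v: v.std(ddof=1)])
    per_ant.columns = ["count", "sd"]
    per_ant = per_ant[per_ant["count"] >= 2]
    hourly = per_ant.groupby(level="hour")["sd"].mean()

    hours = pd.DatetimeIndex(hourly.index)
    values = hourly.to_numpy(dtype=float)

    # covariates at the bin midpoint
    mids = hours + pd.Timedelta(minutes=30)
    hss = np.array(
        [hours_since_sunset(m.to_pydatetime(), tower.lat, tower.lon) for m in mids]
    )
    sincos = np.array([cyclical_hour(h % 24.0) for h in hss])
    night = np.array([is_night(m.to_pydatetime(), tower.lat, tower.lon) for m in mids])
    cov = pd.DataFrame(
        {
            "hours_since_sunset": hss,
            "sin_hss": sincos[:, 0],
            "cos_hss": sincos[:, 1],
            "night": night,
            "date_ordinal": [h.to_pydatetime().toordinal() for h in hours],
        },
        index=hours,
    )
    if weather is not None:
        wx = weather.set_index("timestamp")
        cov["temperature"] = wx["temperature"].reindex(hours).to_numpy()
        cov["wind_speed"] = wx["wind_speed"].reindex(hours).to_numpy()
    else:
        cov["temperature"] = np.nan
        cov["wind_speed"] = np.nan

    gap = np.diff(hours.asi8) / 3.6e12  # hours between successive bins
    segment_id = np.concatenate([[0], np.cumsum(gap > SEGMENT_GAP_HOURS)]).astype(int)
    return HourlyActivitySeries(
        tag_id=track.tag_id,
        hours=hours,
        values=values,
        covariates=cov,
        segment_id=segment_id,
    )


# ---------------------------------------------------------------------------
# HMM machinery
# ---------------------------------------------------------------------------


@dataclass
class HmmFit:
    """Two-state Gaussian HMM with covariate-dependent transitions.

    ``trans_coef[i]`` holds ``(alpha, beta_sin, beta_cos)`` for
    ``logit P(next = active | current = i)`` with i in (rest, active);
    the complementary row entry follows by normalisation, so every
    per-hour transition-matrix row sums to one by construction.
    """

    state_means: np.ndarray  # (mu_rest, mu_active)
    state_sds: np.ndarray
    init_prob: np.ndarray
    trans_coef: np.ndarray  # shape (2, 3)
    log_likelihood: float
    decoded_states: np.ndarray
    n_iters: int
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "state_means": self.state_means.tolist(),
                "state_sds": self.state_sds.tolist(),
                "init_prob": self.init_prob.tolist(),
                "trans_coef": self.trans_coef.tolist(),
                "log_likelihood": self.log_likelihood,
                "n_iters": self.n_iters,
                "converged": self.converged,
            },
            indent=2,
        )


def _segments(series: HourlyActivitySeries) -> list[np.ndarray]:
    return [np.flatnonzero(series.segment_id == s) for s in np.unique(series.segment_id)]


def _design_Z(series: HourlyActivitySeries) -> np.ndarray:
    c = series.covariates
    return np.column_stack(
        [np.ones(len(series)), c["sin_hss"].to_numpy(), c["cos_hss"].to_numpy()]
    )


def transition_matrices(trans_coef: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Per-hour 2x2 transition matrices, rows (rest, active) summing to 1."""
    p = expit(Z @ trans_coef.T)  # (T, 2): P(next=active | current=i)
    A = np.empty((Z.shape[0], 2, 2))
    A[:, :, 1] = p
    A[:, :, 0] = 1.0 - p
    return A


def _emission_logpdf(values: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    v = values[:, None]
    return -0.5 * ((v - mu[None, :]) / sd[None, :]) ** 2 - np.log(
        sd[None, :] * math.sqrt(2.0 * math.pi)
    )


def _forward_backward(values, Z, pi, mu, sd, coef, seg_idx):
    """Scaled forward-backward over one segment.

    Returns (loglik, gamma (T,2), xi (T-1,2,2)); transitions into time t use
    the covariates at time t.
    """
    v = values[seg_idx]
    logB = _emission_logpdf(v, mu, sd)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    bshift = logB.max(axis=1)
    A = transition_matrices(coef, Z[seg_idx])
    T = len(v)
    alpha = np.empty((T, 2))
    c = np.empty(T)
    a0 = pi * B[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A[t]) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.sum(np.log(c)) + np.sum(bshift))
    beta = np.empty((T, 2))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A[t + 1] @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.empty((T - 1, 2, 2))
    for t in range(1, T):
        m = (alpha[t - 1][:, None] * A[t]) * (B[t] * beta[t])[None, :] / c[t]
        xi[t - 1] = m / m.sum()
    return loglik, gamma, xi


def _weighted_logistic(Z, succ, fail, start, max_iter=50, tol=1e-10):
    """Weighted logistic regression with pseudo-counts (M-step helper)."""
    beta = start.copy()
    for _ in range(max_iter):
        p = expit(Z @ beta)
        w = succ + fail
        grad = Z.T @ (succ - w * p)
        H = (Z * (w * p * (1.0 - p))[:, None]).T @ Z + 1e-10 * np.eye(Z.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return np.clip(beta, -25.0, 25.0)


def fit_hmm(
    series: HourlyActivitySeries,
    n_states: int = 2,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> HmmFit:
    """Fit the two-state covariate-transition HMM by EM.

    Independent segments are separate chains sharing parameters, each
    restarting from the initial distribution.  The best of ``restarts``
    seeded initialisations (emission means jittered around a median split)
    is kept, states are relabelled so the active mean exceeds the rest
    mean, and the Viterbi path is decoded.
    """
    if n_states != 2:
        raise ValueError("only two-state models are supported")
    if len(series) < 48:
        raise ValueError(f"fit_hmm: need >= 48 observed hours, got {len(series)}")
    values = series.values.astype(float)
    Z = _design_Z(series)
    segs = _segments(series)
    rng = np.random.default_rng(seed)

    lo = float(np.mean(values[values <= np.median(values)]))
    hi = float(np.mean(values[values > np.median(values)]))
    spread = max(hi - lo, 1e-3)

    best = None
    for r in range(restarts):
        jit = rng.normal(0.0, 0.15 * spread, 2) if r > 0 else np.zeros(2)
        mu = np.array([lo + jit[0], hi + jit[1]])
        sd = np.full(2, max(np.std(values) / 2.0, 1e-3))
        pi = np.array([0.5, 0.5])
        coef = np.array([[-1.4, 0.0, 0.0], [1.4, 0.0, 0.0]])

        ll_prev = -np.inf
        path = []
        converged = False
        failed = False
        for it in range(max_iter):
            tot_ll = 0.0
            gam_all = np.zeros((len(values), 2))
            succ = np.zeros((len(values), 2))  # xi mass into active, per origin
            fail = np.zeros((len(values), 2))
            pi_acc = np.zeros(2)
            for idx in segs:
                ll, gamma, xi = _forward_backward(values, Z, pi, mu, sd, coef, idx)
                if not np.isfinite(ll):
                    failed = True
                    break
                tot_ll += ll
                gam_all[idx] = gamma
                pi_acc += gamma[0]
                # xi[t-1] describes the step into idx[t]
                succ[idx[1:], 0] += xi[:, 0, 1]
                succ[idx[1:], 1] += xi[:, 1, 1]
                fail[idx[1:], 0] += xi[:, 0, 0]
                fail[idx[1:], 1] += xi[:, 1, 0]
            if failed:
                break
            path.append(tot_ll)
            # M-step
            wsum = gam_all.sum(axis=0)
            mu = (gam_all * values[:, None]).sum(axis=0) / wsum
            var = (gam_all * (values[:, None] - mu[None, :]) ** 2).sum(axis=0) / wsum
            sd = np.sqrt(np.maximum(var, 1e-8))
            pi = pi_acc / len(segs)
            pi = np.clip(pi, 1e-8, None)
            pi /= pi.sum()
            for i in range(2):
                coef[i] = _weighted_logistic(Z, succ[:, i], fail[:, i], coef[i])
            if tot_ll - ll_prev < tol and it > 0:
                converged = True
                ll_prev = tot_ll
                break
            ll_prev = tot_ll
        if failed or not path:
            continue
        if best is None or ll_prev > best[0]:
            best = (ll_prev, mu, sd, pi, coef.copy(), np.array(path), converged, len(path))
    if best is None:
        raise RuntimeError("fit_hmm: all restarts produced non-finite likelihoods")

    ll, mu, sd, pi, coef, path, converged, n_iters = best
    # relabel so that state 1 = active = larger mean
    if mu[0] > mu[1]:
        mu = mu[::-1].copy()
        sd = sd[::-1].copy()
        pi = pi[::-1].copy()
        # P(next = new active | prev = new i) = P(next = old rest | prev = old 1-i)
        coef = np.vstack([-coef[1], -coef[0]])

    fit = HmmFit(
        state_means=mu,
        state_sds=sd,
        init_prob=pi,
        trans_coef=coef,
        log_likelihood=float(ll),
        decoded_states=np.empty(0, dtype=int),
        n_iters=n_iters,
        converged=converged,
        loglik_path=path,
    )
    fit.decoded_states = decode_states(fit, series)
    return fit


def forward_loglik(fit_or_params, series: HourlyActivitySeries) -> float:
    """Marginal log-likelihood of the series under the model (forward pass)."""
    mu, sd, pi, coef = _unpack(fit_or_params)
    Z = _design_Z(series)
    total = 0.0
    for idx in _segments(series):
        ll, _, _ = _forward_backward(series.values.astype(float), Z, pi, mu, sd, coef, idx)
        total += ll
    return total


def _unpack(fit_or_params):
    if isinstance(fit_or_params, HmmFit):
        f = fit_or_params
        return f.state_means, f.state_sds, f.init_prob, f.trans_coef
    mu, sd, pi, coef = fit_or_params
    return np.asarray(mu, float), np.asarray(sd, float), np.asarray(pi, float), np.asarray(coef, float)


def decode_states(fit_or_params, series: HourlyActivitySeries) -> np.ndarray:
    """Most probable state path (Viterbi) per segment; 0 = rest, 1 = active."""
    mu, sd, pi, coef = _unpack(fit_or_params)
    values = series.values.astype(float)
    Z = _design_Z(series)
    out = np.empty(len(values), dtype=int)
    for idx in _segments(series):
        logB = _emission_logpdf(values[idx], mu, sd)
        with np.errstate(divide="ignore"):
            logA = np.log(transition_matrices(coef, Z[idx]))
            logpi = np.log(pi)
        T = len(idx)
        delta = np.empty((T, 2))
        back = np.zeros((T, 2), dtype=int)
        delta[0] = logpi + logB[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logA[t]
            back[t] = np.argmax(cand, axis=0)
            delta[t] = np.max(cand, axis=0) + logB[t]
        states = np.empty(T, dtype=int)
        states[T - 1] = int(np.argmax(delta[T - 1]))
        for t in range(T - 2, -1, -1):
            states[t] = back[t + 1][states[t + 1]]
        out[idx] = states
    return out


# ---------------------------------------------------------------------------
# Decoded-state trends
# ---------------------------------------------------------------------------


@dataclass
class TrendFit:
    variable: str
    slope: float
    intercept: float
    degenerate: bool


TREND_VARS = ("date_ordinal", "hours_since_sunset", "wind_speed", "temperature")


def state_condition_trends(
    decoded: np.ndarray,
    covariates: pd.DataFrame,
    night_only: bool = True,
    variables: Sequence[str] = TREND_VARS,
) -> dict[str, TrendFit]:
    """Univariate logistic trends of the active state in night-hour conditions.

    Restricts to hours between sunset and sunrise (``night`` covariate) and
    fits ``P(active)`` against each variable separately.  All-one-state
    input, perfect separation, or a missing covariate yields a flagged
    degenerate fit rather than an exception.
    """
    import statsmodels.api as sm

    mask = covariates["night"].to_numpy(bool) if night_only else np.ones(len(decoded), bool)
    y = np.asarray(decoded)[mask]
    out: dict[str, TrendFit] = {}
    for var in variables:
        x = covariates.loc[mask, var].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if y[ok].size == 0 or len(np.unique(y[ok])) < 2:
            out[var] = TrendFit(var, float("nan"), float("nan"), True)
            continue
        # centre the covariate for numerical stability (slope unchanged;
        # intercept refers to the covariate's night-hour mean)
        X = sm.add_constant(x[ok] - x[ok].mean())
        try:
            res = sm.Logit(y[ok], X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 1e3:
                raise ValueError("separation")
            out[var] = TrendFit(var, float(res.params[1]), float(res.params[0]), False)
        except Exception:
            out[var] = TrendFit(var, float("nan"), float("nan"), True)
    return out
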