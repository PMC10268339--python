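"""Over-water crossing detection and the use-availability selection model.

A same-night pair of detections on opposite shores of a named water body is
direct evidence that the bat flew across it.  Each crossing's midpoint time
(rounded to the nearest whole hour, half-up) becomes a *used* point in a
use-availability (resource selection) design; for every used point, ten
*available* hours are drawn uniformly from the tag's first 40 days at
liberty.  Atmospheric covariates are attached to both, and the binary
used/available response is modelled with a logistic GLMM — fixed effects
for the covariates, a Gaussian random intercept per tag — whose marginal
likelihood is integrated by adaptive Gauss-Hermite quadrature.  All-subsets
AICc selection (a "dredge") ranks every additive combination of the ten
atmospheric covariates, with hours-since-sunset held in every model.

Because availability is sampled rather than exhaustive, the fitted
intercept has no absolute interpretation; predictions are *relative*
probabilities of over-water flight.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from statsmodels.tools.numdiff import approx_hess

from .telemetry import Deployment, Tower, Track, hours_since_sunset, is_night, night_id

logger = logging.getLogger(__name__)

__all__ = [
    "CANDIDATE_VARS",
    "CrossingEvent",
    "RsfFit",
    "detect_crossings",
    "round_half_up_hour",
    "sample_available",
    "build_use_avail",
    "attach_covariates",
    "fit_logistic_irls",
    "fit_mixed_logit",
    "enumerate_model_subsets",
    "dredge_aicc",
    "aicc",
    "marginal_effects",
    "write_crossings",
]

#: The ten atmospheric candidate covariates of the selection model.
CANDIDATE_VARS = (
    "wind_speed",
    "temperature",
    "precipitation",
    "visibility",
    "pressure",
    "wind_x",
    "wind_y",
    "d_wind_1h",
    "d_temp_1h",
    "d_pressure_24h",
)

ALWAYS_IN = ("hours_since_sunset",)


# ---------------------------------------------------------------------------
# Crossing detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossingEvent:
    tag_id: str
    water_body: str
    night: date
    departure_time: datetime
    arrival_time: datetime
    departure_tower: str
    arrival_tower: str
    midpoint_hour: datetime


def round_half_up_hour(ts: datetime) -> datetime:
    """Round to the nearest whole hour; exactly :30 rounds up."""
    base = ts.replace(minute=0, second=0, microsecond=0)
    frac = (ts - base).total_seconds()
    return base + timedelta(hours=1) if frac >= 1800.0 else base


def detect_crossings(
    tracks: Iterable[Track], towers: Iterable[Tower]
) -> list[CrossingEvent]:
    """Find same-night transits across each labelled water body.

    For each tag, water body, and night: the detection sequence at that
    body's shore towers is reduced to its side labels; every side change
    within one night emits an event whose departure is the last detection
    on the origin side and whose arrival is the first detection on the
    opposite side.  A back-and-forth transit in one night yields two
    events.
    """
    tower_list = list(towers)
    events: list[CrossingEvent] = []
    bodies: dict[str, dict[str, str]] = {}
    for t in tower_list:
        for wb, side in t.water_sides.items():
            if not side:
                logger.warning(
                    "tower %s borders %s but has no side label; ignored for that body",
                    t.tower_id,
                    wb,
                )
                continue
            bodies.setdefault(wb, {})[t.tower_id] = side

    for track in tracks:
        dep = track.deployment
        for wb, side_of in bodies.items():
            shore = [d for d in track.detections if d.tower_id in side_of]
            if not shore:
                continue
            tower_ix = {t.tower_id: t for t in tower_list}
            by_night: dict[date, list] = {}
            for d in shore:
                tw = tower_ix[d.tower_id]
                n = night_id(d.timestamp, tw.lat, tw.lon)
                by_night.setdefault(n, []).append(d)
            for n, dets in sorted(by_night.items()):
                dets.sort(key=lambda d: d.timestamp)
                prev = dets[0]
                for cur in dets[1:]:
                    if side_of[cur.tower_id] != side_of[prev.tower_id]:
                        if cur.timestamp > prev.timestamp:
                            mid = prev.timestamp + (cur.timestamp - prev.timestamp) / 2
                            events.append(
                                CrossingEvent(
                                    tag_id=track.tag_id,
                                    water_body=wb,
                                    night=n,
                                    departure_time=prev.timestamp,
                                    arrival_time=cur.timestamp,
                                    departure_tower=prev.tower_id,
                                    arrival_tower=cur.tower_id,
                                    midpoint_hour=round_half_up_hour(mid),
                                )
                            )
                    prev = cur
    return events


def write_crossings(events: Sequence[CrossingEvent], path) -> None:
    rows = [
        {
            "tag_id": e.tag_id,
            "water_body": e.water_body,
            "night": e.night.isoformat(),
            "departure_time": e.departure_time.astimezone(timezone.utc).isoformat(),
            "arrival_time": e.arrival_time.astimezone(timezone.utc).isoformat(),
            "departure_tower": e.departure_tower,
            "arrival_tower": e.arrival_tower,
            "midpoint_hour": e.midpoint_hour.astimezone(timezone.utc).isoformat(),
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Availability sampling and covariates
# ---------------------------------------------------------------------------


def sample_available(
    events: Sequence[CrossingEvent],
    deployments: Sequence[Deployment],
    ratio: int = 10,
    horizon_days: float = 40.0,
    seed: int = 0,
) -> list[tuple[str, datetime]]:
    """Draw ``ratio`` available hours per used point, per contributing tag.

    Candidate hours are the whole hours in each tag's ``[release, release +
    horizon_days)`` window, excluding the tag's own used midpoints (sampled
    without replacement so no available hour repeats within a tag).
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    dep_ix = {d.tag_id: d for d in deployments}
    used_by_tag: dict[str, list[datetime]] = {}
    for e in events:
        used_by_tag.setdefault(e.tag_id, []).append(e.midpoint_hour)
    rng = np.random.default_rng(seed)
    out: list[tuple[str, datetime]] = []
    for tag_id in sorted(used_by_tag):
        if tag_id not in dep_ix:
            raise KeyError(f"sample_available: no deployment for tag {tag_id!r}")
        dep = dep_ix[tag_id]
        start = pd.Timestamp(dep.release_time).ceil("h")
        end = pd.Timestamp(dep.release_time) + pd.Timedelta(days=horizon_days)
        candidates = pd.date_range(start, end, freq="h", inclusive="left")
        used = set(pd.Timestamp(u) for u in used_by_tag[tag_id])
        candidates = candidates[~candidates.isin(used)]
        n_draw = ratio * len(used_by_tag[tag_id])
        if n_draw > len(candidates):
            raise ValueError(
                f"sample_available: tag {tag_id} needs {n_draw} hours but only "
                f"{len(candidates)} candidates exist"
            )
        pick = rng.choice(len(candidates), size=n_draw, replace=False)
        out.extend((tag_id, candidates[int(i)].to_pydatetime()) for i in sorted(pick))
    return out


def build_use_avail(
    events: Sequence[CrossingEvent], available: Sequence[tuple[str, datetime]]
) -> pd.DataFrame:
    """Stack used midpoints and available hours into one response table."""
    rows = [
        {"tag_id": e.tag_id, "timestamp": pd.Timestamp(e.midpoint_hour), "used": 1}
        for e in events
    ]
    rows += [
        {"tag_id": tag, "timestamp": pd.Timestamp(ts), "used": 0} for tag, ts in available
    ]
    df = pd.DataFrame(rows)
    df["timestamp"] = pd.DatetimeIndex(df["timestamp"], tz="UTC") if len(df) else df["timestamp"]
    return df


def attach_covariates(
    rows: pd.DataFrame,
    weather: pd.DataFrame,
    deployments: Sequence[Deployment],
) -> pd.DataFrame:
    """Attach the atmospheric covariates to used/available rows.

    Instantaneous covariates come from the weather record at the row's
    hour.  Wind is resolved into zonal/meridional components with the
    convention that winds blowing FROM the east (``wind_x``) and FROM the
    north (``wind_y``) are positive.  One-hour deltas subtract the previous
    hour's record; the 24-h pressure delta subtracts the previous night's
    mean night-time pressure from the current night's.  Hours since sunset
    and night grouping use the tag's release location.
    """
    dep_ix = {d.tag_id: d for d in deployments}
    wx = weather.set_index("timestamp").sort_index()
    out = rows.copy().reset_index(drop=True)

    hss = np.empty(len(out))
    inst = {c: np.empty(len(out)) for c in
            ("temperature", "wind_speed", "precipitation", "visibility", "pressure")}
    wind_x = np.empty(len(out))
    wind_y = np.empty(len(out))
    d_wind = np.empty(len(out))
    d_temp = np.empty(len(out))
    d_press = np.empty(len(out))

    # per-tag cache of nightly mean pressure (night hours only)
    night_press_cache: dict[str, dict[date, float]] = {}

    def nightly_pressure(dep: Deployment) -> dict[date, float]:
        if dep.tag_id in night_press_cache:
            return night_press_cache[dep.tag_id]
        lo = dep.release_time - timedelta(days=3)
        hi = dep.release_time + timedelta(days=60)
        sub = wx.loc[(wx.index >= lo) & (wx.index <= hi)]
        nights: dict[date, list[float]] = {}
        for ts, p in zip(sub.index, sub["pressure"].to_numpy()):
            t = ts.to_pydatetime()
            if is_night(t, dep.release_lat, dep.release_lon):
                nights.setdefault(
                    night_id(t, dep.release_lat, dep.release_lon), []
                ).append(float(p))
        means = {n: float(np.mean(v)) for n, v in nights.items()}
        night_press_cache[dep.tag_id] = means
        return means

    for i, r in enumerate(out.itertuples(index=False)):
        tag = r.tag_id
        if tag not in dep_ix:
            raise KeyError(f"attach_covariates: no deployment for tag {tag!r}")
        dep = dep_ix[tag]
        ts = pd.Timestamp(r.timestamp)
        if ts not in wx.index:
            raise KeyError(f"attach_covariates: missing weather hour {ts.isoformat()}")
        prev = ts - pd.Timedelta(hours=1)
        if prev not in wx.index:
            raise KeyError(f"attach_covariates: missing weather hour {prev.isoformat()}")
        w = wx.loc[ts]
        wp = wx.loc[prev]
        t = ts.to_pydatetime()
        hss[i] = hours_since_sunset(t, dep.release_lat, dep.release_lon)
        for c in inst:
            inst[c][i] = float(w[c])
        theta = math.radians(float(w["wind_dir"]))
        wind_x[i] = float(w["wind_speed"]) * math.sin(theta)
        wind_y[i] = float(w["wind_speed"]) * math.cos(theta)
        d_wind[i] = float(w["wind_speed"]) - float(wp["wind_speed"])
        d_temp[i] = float(w["temperature"]) - float(wp["temperature"])
        means = nightly_pressure(dep)
        n = night_id(t, dep.release_lat, dep.release_lon)
        prev_n = n - timedelta(days=1)
        if n not in means or prev_n not in means:
            raise KeyError(
                f"attach_covariates: nightly pressure unavailable around {ts.isoformat()}"
            )
        d_press[i] = means[n] - means[prev_n]

    out["hours_since_sunset"] = hss
    for c in inst:
        out[c] = inst[c]
    out["wind_x"] = wind_x
    out["wind_y"] = wind_y
    out["d_wind_1h"] = d_wind
    out["d_temp_1h"] = d_temp
    out["d_pressure_24h"] = d_press
    return out


# ---------------------------------------------------------------------------
# Mixed logistic model (random intercept per tag, adaptive Gauss-Hermite)
# ---------------------------------------------------------------------------


@dataclass
class RsfFit:
    variable_subset: tuple[str, ...]
    beta: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    random_intercept_sd: float
    log_likelihood: float
    aicc: float
    n_used: int
    n_available: int
    converged: bool
    cov: np.ndarray | None = None  # fixed-effect covariance, order = names
    names: tuple[str, ...] = ()

    @property
    def delta_aicc(self) -> float:  # filled by dredge
        return getattr(self, "_delta_aicc", float("nan"))


class ConvergenceError(RuntimeError):
    pass


def _design(rows: pd.DataFrame, variables: Sequence[str]):
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[v].to_numpy(dtype=float) for v in variables]
    )
    y = rows["used"].to_numpy(dtype=float)
    groups, _ = pd.factorize(rows["tag_id"], sort=True)
    names = ("intercept", *variables)
    return X, y, groups, names


def fit_logistic_irls(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, float]:
    """Plain logistic regression by Newton-Raphson (IRLS).

    Returns ``(beta, log_likelihood)``; raises :class:`ConvergenceError` on
    apparent complete separation or non-convergence.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X + 1e-12 * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge; |grad|={np.max(np.abs(X.T @ (y - expit(X @ beta)))):.3g}"
        )
    if np.max(np.abs(beta)) > 50.0:
        raise ConvergenceError("complete separation suspected (unbounded coefficients)")
    eta = X @ beta
    ll = float(np.sum(y * log_expit(eta) + (1.0 - y) * log_expit(-eta)))
    return beta, ll


_GH_NODES = 15


def _marginal_nll(theta, X, y, groups, n_groups, gh_t, gh_logw):
    """Negative marginal log-likelihood via adaptive Gauss-Hermite.

    The random intercept for group j is ``sigma * u_j`` with u ~ N(0,1).
    Per group the integrand's mode is found by a vectorised 1-D Newton
    scheme; nodes are recentred/rescaled there (standard adaptive GHQ).
    """
    beta, sigma = theta[:-1], abs(theta[-1])
    eta0 = X @ beta
    u = np.zeros(n_groups)
    for _ in range(40):
        mu = expit(eta0 + sigma * u[groups])
        g1 = np.bincount(groups, sigma * (y - mu), minlength=n_groups) - u
        g2 = -np.bincount(groups, sigma * sigma * mu * (1.0 - mu), minlength=n_groups) - 1.0
        step = g1 / g2
        u = u - step
        if np.max(np.abs(step)) < 1e-11:
            break
    mu = expit(eta0 + sigma * u[groups])
    g2 = -np.bincount(groups, sigma * sigma * mu * (1.0 - mu), minlength=n_groups) - 1.0
    s = 1.0 / np.sqrt(-g2)  # curvature scale at the mode

    # log-integrand at shifted nodes: h(u) = sum_i loglik_i(eta0 + sigma u) - u^2/2;
    # with u = mode + s t:  log L = log s + logsumexp_k[log w_k + t_k^2/2 + h] - log sqrt(2 pi)
    nodes = u[:, None] + s[:, None] * gh_t[None, :]  # (G, K)
    K = nodes.shape[1]
    etak = eta0[:, None] + sigma * nodes[groups, :]  # (n, K)
    sgn = np.where(y[:, None] == 1.0, 1.0, -1.0)
    ll_i = log_expit(sgn * etak)
    flat_idx = (groups[:, None] * K + np.arange(K)[None, :]).ravel()
    h = np.bincount(flat_idx, ll_i.ravel(), minlength=n_groups * K).reshape(n_groups, K)
    h -= 0.5 * nodes**2
    val = h + (gh_logw + 0.5 * gh_t**2)[None, :] + np.log(s)[:, None]
    m = val.max(axis=1)
    logL = m + np.log(np.sum(np.exp(val - m[:, None]), axis=1)) - 0.5 * math.log(2 * math.pi)
    return -float(np.sum(logL))


def fit_mixed_logit(
    rows: pd.DataFrame,
    variable_subset: Sequence[str],
    *,
    pin_random_sd: float | None = None,
    n_quad: int = _GH_NODES,
    compute_se: bool = True,
    start: np.ndarray | None = None,
    coef_bound: float | None = None,
) -> RsfFit:
    """Fit the used/available logistic model with a per-tag random intercept.

    The marginal likelihood integrates the Gaussian random intercept by
    adaptive Gauss-Hermite quadrature with ``n_quad`` nodes.  With
    ``pin_random_sd=0`` the model degenerates to ordinary logistic
    regression (fit by Newton-Raphson), which is the documented reduction
    used to validate the optimiser.  Standard errors come from the inverse
    observed information; Wald z and two-sided normal p-values accompany
    each fixed effect.

    Apparent complete separation raises :class:`ConvergenceError` unless
    ``coef_bound`` is given, in which case fixed effects are constrained to
    ``[-coef_bound, coef_bound]`` and the fit is returned with a warning —
    the behaviour an all-subsets dredge needs for quasi-separated subsets
    (e.g. a sparse covariate never observed at a used point).
    """
    if rows["used"].nunique() < 2:
        raise ValueError("fit_mixed_logit: need both used and available rows")
    if rows["tag_id"].nunique() < 2:
        raise ValueError("fit_mixed_logit: need >= 2 tags for a random intercept")
    X, y, groups, names = _design(rows, variable_subset)
    n_groups = int(groups.max()) + 1
    n = len(y)

    if pin_random_sd is not None and pin_random_sd == 0.0:
        beta, ll = fit_logistic_irls(X, y)
        cov = np.linalg.inv((X * (expit(X @ beta) * (1 - expit(X @ beta)))[:, None]).T @ X)
        se = np.sqrt(np.diag(cov))
        k = X.shape[1] + 1
        return _pack_fit(names, beta, se, 0.0, ll, k, n, rows, True, cov, variable_subset)

    # probabilists' Gauss-Hermite: integral f(t) e^{-t^2/2} dt ~ sum w_k f(t_k)
    gh_t, gh_w = hermegauss(n_quad)
    gh_logw = np.log(gh_w)

    if start is None:
        try:
            beta0, _ = fit_logistic_irls(X, y)
        except ConvergenceError:
            beta0 = np.zeros(X.shape[1])
        start = np.append(beta0, 0.5)
    if pin_random_sd is not None:
        # profile fit with sigma held fixed
        def nll_b(b):
            return _marginal_nll(
                np.append(b, pin_random_sd), X, y, groups, n_groups, gh_t, gh_logw
            )

        res = minimize(nll_b, start[:-1], method="BFGS", options={"gtol": 1e-7, "maxiter": 400})
        theta = np.append(res.x, pin_random_sd)
        free = slice(0, X.shape[1])
    else:
        def nll(t):
            return _marginal_nll(t, X, y, groups, n_groups, gh_t, gh_logw)

        b = coef_bound if coef_bound is not None else None
        res = minimize(
            nll,
            np.clip(start, -(b or np.inf), b or np.inf),
            method="L-BFGS-B",
            bounds=[(-b, b) if b else (None, None)] * X.shape[1] + [(1e-6, None)],
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        theta = res.x
        free = slice(0, X.shape[1] + 1)

    beta = theta[: X.shape[1]]
    sigma = abs(theta[-1])
    ll = -_marginal_nll(theta, X, y, groups, n_groups, gh_t, gh_logw)
    at_bound = coef_bound is not None and np.max(np.abs(beta)) >= coef_bound - 1e-6
    if at_bound:
        logger.warning(
            "fit_mixed_logit: coefficients at the +/-%.0f bound for subset %s "
            "(quasi-separation)", coef_bound, tuple(variable_subset)
        )
    if coef_bound is None and np.max(np.abs(beta)) > 50.0:
        raise ConvergenceError("complete separation suspected (unbounded coefficients)")
    if (
        not at_bound
        and not res.success
        and np.max(np.abs(res.jac if res.jac is not None else [np.inf])) > 1e-2
    ):
        raise ConvergenceError(
            f"mixed logit did not converge: |grad|={np.max(np.abs(res.jac)):.3g}"
        )

    se = np.full(X.shape[1], np.nan)
    cov_b = None
    if compute_se:
        def nll_theta(t):
            return _marginal_nll(t, X, y, groups, n_groups, gh_t, gh_logw)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess(theta, nll_theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        cov_b = cov[: X.shape[1], : X.shape[1]]
        se = np.sqrt(np.clip(np.diag(cov_b), 0.0, None))

    k = X.shape[1] + 1  # fixed effects (incl. intercept) + random-intercept SD
    return _pack_fit(names, beta, se, sigma, ll, k, n, rows, True, cov_b, variable_subset)


def _pack_fit(names, beta, se, sigma, ll, k, n, rows, converged, cov, subset) -> RsfFit:
    from scipy.stats import norm

    beta_d = dict(zip(names, map(float, beta)))
    se_d = dict(zip(names, map(float, se)))
    z_d = {m: (beta_d[m] / se_d[m] if se_d.get(m) and np.isfinite(se_d[m]) and se_d[m] > 0 else float("nan")) for m in names}
    p_d = {m: float(2.0 * norm.sf(abs(z_d[m]))) if np.isfinite(z_d[m]) else float("nan") for m in names}
    return RsfFit(
        variable_subset=tuple(subset),
        beta=beta_d,
        se=se_d,
        z=z_d,
        p=p_d,
        random_intercept_sd=float(sigma),
        log_likelihood=float(ll),
        aicc=aicc(ll, k, n),
        n_used=int(rows["used"].sum()),
        n_available=int((1 - rows["used"]).sum()),
        converged=converged,
        cov=cov,
        names=tuple(names),
    )


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: ``-2 ll + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ---------------------------------------------------------------------------
# All-subsets AICc selection
# ---------------------------------------------------------------------------


def enumerate_model_subsets(
    candidate_vars: Sequence[str] = CANDIDATE_VARS,
    always_in: Sequence[str] = ALWAYS_IN,
) -> list[tuple[str, ...]]:
    """All additive combinations of the candidates, each plus ``always_in``."""
    if not candidate_vars:
        raise ValueError("candidate set must be non-empty")
    out = []
    for r in range(len(candidate_vars) + 1):
        for combo in itertools.combinations(candidate_vars, r):
            out.append(tuple(always_in) + combo)
    return out


@dataclass
class DredgeResult:
    fits: list[RsfFit]  # ascending AICc
    delta_aicc: list[float]
    competitive: list[RsfFit] = field(default_factory=list)  # delta < 2

    @property
    def best(self) -> RsfFit:
        return self.fits[0]


def dredge_aicc(
    rows: pd.DataFrame,
    candidate_vars: Sequence[str] = CANDIDATE_VARS,
    always_in: Sequence[str] = ALWAYS_IN,
    compute_se_competitive: bool = True,
) -> DredgeResult:
    """Fit every additive subset of the candidates and rank by AICc.

    Each model also carries ``always_in`` and the per-tag random intercept.
    Models whose AICc correction is undefined (n <= k+1) are excluded with
    a warning; quasi-separated subsets are fitted with coefficients bounded
    at +/-40 (warned) rather than dropped, so the candidate count matches
    the enumeration.  Fits skip standard errors for speed; the competitive
    set (ΔAICc < 2) is refit with standard errors.
    """
    subsets = enumerate_model_subsets(candidate_vars, always_in)
    # warm start: the global-model fit's sigma seeds every subset fit
    full = fit_mixed_logit(rows, subsets[-1], compute_se=False, coef_bound=40.0)
    sigma0 = max(full.random_intercept_sd, 0.05)

    fits: list[RsfFit] = []
    n = len(rows)
    for subset in subsets:
        k = len(subset) + 2  # intercept + vars + random SD
        if n <= k + 1:
            logger.warning("dredge: subset %s infeasible (n=%d, k=%d); skipped", subset, n, k)
            continue
        X, y, groups, _ = _design(rows, subset)
        try:
            beta0, _ll = fit_logistic_irls(X, y)
        except ConvergenceError:
            beta0 = np.zeros(X.shape[1])
        fit = fit_mixed_logit(
            rows, subset, compute_se=False, start=np.append(beta0, sigma0), coef_bound=40.0
        )
        fits.append(fit)
    fits.sort(key=lambda f: f.aicc)
    best = fits[0].aicc
    deltas = [f.aicc - best for f in fits]
    competitive = []
    for f, d in zip(fits, deltas):
        f._delta_aicc = d
        if d < 2.0:
            if compute_se_competitive:
                refit = fit_mixed_logit(
                    rows, f.variable_subset, compute_se=True, coef_bound=40.0
                )
                refit._delta_aicc = d
                competitive.append(refit)
            else:
                competitive.append(f)
    return DredgeResult(fits=fits, delta_aicc=deltas, competitive=competitive)


def dredge_table(result: DredgeResult) -> pd.DataFrame:
    """One row per fitted subset with AICc and ΔAICc, ascending."""
    return pd.DataFrame(
        {
            "variables": ["+".join(f.variable_subset) for f in result.fits],
            "k_fixed": [len(f.variable_subset) + 1 for f in result.fits],
            "log_likelihood": [f.log_likelihood for f in result.fits],
            "aicc": [f.aicc for f in result.fits],
            "delta_aicc": result.delta_aicc,
            "random_intercept_sd": [f.random_intercept_sd for f in result.fits],
        }
    )


# ---------------------------------------------------------------------------
# Marginal effects
# ---------------------------------------------------------------------------


def marginal_effects(
    fit: RsfFit, rows: pd.DataFrame, variable: str, grid_size: int = 100
) -> pd.DataFrame:
    """Relative-probability curve for one covariate, others at their means.

    Predictions hold every other fixed effect at its sample mean and the
    random intercept at zero; the 95% interval is the delta-method normal
    interval on the linear predictor, inverse-logit transformed (so the
    band always brackets the point estimate).
    """
    if variable not in fit.variable_subset:
        raise ValueError(f"marginal_effects: {variable!r} not in the fitted model")
    if fit.cov is None:
        raise ValueError("marginal_effects: fit has no covariance; refit with compute_se=True")
    grid = np.linspace(rows[variable].min(), rows[variable].max(), grid_size)
    names = fit.names
    Xp = np.empty((grid_size, len(names)))
    for j, nm in enumerate(names):
        if nm == "intercept":
            Xp[:, j] = 1.0
        elif nm == variable:
            Xp[:, j] = grid
        else:
            Xp[:, j] = rows[nm].mean()
    b = np.array([fit.beta[nm] for nm in names])
    eta = Xp @ b
    var = np.einsum("ij,jk,ik->i", Xp, fit.cov, Xp)
    half = 1.959963984540054 * np.sqrt(np.clip(var, 0.0, None))
    return pd.DataFrame(
        {
            "value": grid,
            "prob": expit(eta),
            "lower95": expit(eta - half),
            "upper95": expit(eta + half),
        }
    )
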