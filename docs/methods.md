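# Methods

This note documents the models, rules, and numerical choices behind
`batmove`, and what the synthetic-data generator does and does not emulate.

## The analysis problem

Automated VHF telemetry networks (Motus-style) record timestamped
detections of coded transmitters at fixed receiver towers: tag id, time,
tower, antenna, signal strength, and the run length of consecutive
decodings. From such tables, for a fall cohort of tagged migratory bats on
a coastal plain with two large bays, the pipeline answers three questions:

1. **Movement categories** — which bats migrated (one-way displacement
   > 50 km), which showed site residency (> 1 night of detections within
   12 km of the release point), which did both, and which made a long
   round trip; plus bearings and minimum residency times.
2. **Over-water flight** — when bats crossed a bay (same-night detections
   on opposite shores), and which atmospheric conditions are associated
   with crossing, estimated in a use-availability (resource-selection)
   design with a logistic GLMM.
3. **Resident activity** — for bats in long site residency, an hourly
   rest/active classification from signal-strength variability, via a
   two-state hidden Markov model whose transition probabilities follow the
   diel cycle, and the decoded states' trends in night-hour conditions.

## Detection cleaning

Three filters are applied, in order, before any inference:

* **Run-length filter** (`min_run = 4`): only detections belonging to runs
  of more than 3 sequential decodings are kept; shorter runs are treated
  as decoder noise. The inequality is strict (> 3).
* **Implausibility filter** (`max_km = 1000`): a detection is removed when
  its tower is more than 1,000 km from the release point *and* from the
  towers of both temporal neighbours, iterated to a fixed point. This
  removes lone spurious hits at absurd distances while keeping genuine
  long hops that are anchored to the release point or to each other.
* **Tag-drop trim** (`steady_days = 7`): if the terminal contiguous
  segment at a single tower/antenna spans at least 7 days and its signal
  standard deviation is at most `steady_sd_tol` (default 5% of the whole
  track's signal SD), the segment is removed as a shed transmitter. The
  SD tolerance operationalises a judgement that is usually made by eye;
  5% is deliberately conservative, and the parameter is exposed.

All filters are idempotent and return subsequences of their input. Time is
stored UTC throughout; distances use a spherical Earth with R = 6371.0 km
(worst-case error versus an ellipsoid is far below the 50/1000 km decision
thresholds). Sunset and sunrise use the NOAA solar-position equations at
zenith 90.833°; the test suite checks them against an independent
Fourier-series (Spencer) formulation to within two minutes.

A *night* is labelled by the calendar date of its sunset; every instant
from that sunset to the next sunrise carries that date, and daytime
instants carry the upcoming sunset's date, so the label increments exactly
once per day, at sunrise.

## Movement classification

The release point counts as the track's initial location. A *hop* is a
later location more than 50 km from an earlier one; a hop is *returned*
when a subsequent detection comes back within 12 km of the hop's origin.
Documented round trips take priority: if any hop is returned, the track is
a long-distance return; otherwise any hop makes it a migrant. Without this
priority rule the return leg of a round trip (> 50 km with no later
return) would itself masquerade as one-way migration. "Nearby" in the
return rule reuses the 12-km residency radius; both radii are parameters.

Minimum residency time is the calendar-day difference between the tagging
date and the last local-detection date (a single-day resident scores 0,
and residency additionally requires local detections on more than one
night). Cohort bearings use the circular (vector) mean, with the printed
min/max as plain order statistics on [0, 360); a zero-resultant bearing
set is flagged undefined rather than averaged. Residency quantiles use
linear interpolation.

## Over-water selection model

Crossing events are same-night detections on opposite shore towers of a
named water body; shore membership is declared tower metadata (two legal
side labels per body), not computed geometry. Each side change within a
night emits one event — a same-night round trip is two events. The event
time is the departure/arrival midpoint rounded to the nearest whole hour,
half-up (the rounding convention is a package choice; only "nearest whole
hour" is externally specified).

For each tag contributing events, 10 available hours per used hour are
drawn uniformly without replacement from the tag's whole hours in
[release, release + 40 days), excluding the tag's own used hours. The ten
candidate atmospheric covariates are wind speed (m/s), temperature (°C),
precipitation (accumulated cm/h), visibility (0–16 km), pressure (kPa),
the zonal and meridional wind components (positive = wind *from* the east
and *from* the north, i.e. `wind_x = v sin θ`, `wind_y = v cos θ` with θ
the meteorological direction), the one-hour changes in wind speed and
temperature, and the 24-h change in mean night-time pressure (current
night minus previous night). Hours-since-sunset is an eleventh covariate
held in every model. Sunset context and night grouping use the tag's
release location; weather comes from the nearest station (the generator
collocates a single station, so no interpolation is performed).

The response (used = 1, available = 0) is modelled as

    logit P(used) = x'β + u_tag,   u_tag ~ N(0, σ²)

and the marginal likelihood integrates u by **adaptive Gauss–Hermite
quadrature** (15 nodes; per-group mode and curvature found by a vectorised
Newton scheme, nodes recentred and rescaled there). Optimisation is
L-BFGS-B on (β, σ) with σ ≥ 1e-6; standard errors come from the inverse
observed information (numerical Hessian), with Wald z and two-sided normal
p-values. With σ pinned to zero the model reduces exactly to ordinary
logistic regression, which is fit by Newton–Raphson and checked against an
independent IRLS implementation in the tests. Because availability is
sampled (case-control), the intercept is not interpretable as an absolute
probability; predictions are relative.

**All-subsets selection.** Every additive combination of the ten candidate
covariates (2¹⁰ = 1,024 models, each also carrying hours-since-sunset and
the random intercept) is fitted and ranked by AICc with
k = n_fixed_effects (incl. intercept) + 1 for the random-intercept SD and
n = total rows. Models with ΔAICc < 2 form the competitive set and are
refit with standard errors. Subsets where a sparse covariate is
quasi-separated (e.g. precipitation positive at no used point) are fitted
with fixed effects bounded at ±40 and a logged warning rather than
dropped, so the candidate count always equals the enumeration; direct
single-model fits instead raise on apparent separation. Marginal-effect
curves hold all other covariates at their sample means and the random
intercept at zero, with 95% delta-method intervals on the linear predictor
transformed through the inverse logit (so the band always brackets the
point estimate).

## Activity index and hidden Markov model

Bats retained for the activity analysis are residents for more than
20 days whose local detection dates never skip more than 2 consecutive
days. Analysis is restricted to the local tower with the most detections.
Per antenna, signals are divided by that antenna's overall SD (zero-SD
antennas are excluded with a warning), binned by clock hour, and the
within-hour SD of scaled signal is computed for antennas with at least two
detections in the hour; antenna values are then averaged per hour over the
antennas observed that hour. Hours observed on no antenna are *missing*,
not zero — zero would masquerade as rest. The construction is invariant to
any positive per-antenna gain. Gaps longer than 6 hours split the series
into independent segments that share parameters but restart from the
initial state distribution; steps across shorter in-segment gaps are
treated as single transitions.

The two-state model has Gaussian emissions (μ_rest, σ_rest, μ_active,
σ_active) and per-hour transition matrices

    P(next = active | current = i) = logit⁻¹(α_i + β_sin,i s_t + β_cos,i c_t)

where (s_t, c_t) = (sin, cos)(2π·hss_t/24) and hss is hours-since-sunset
at the hour-bin midpoint, so each row sums to one by construction. Fitting
is EM: scaled forward–backward with per-hour transition matrices in the
E-step; weighted Gaussian updates, a weighted logistic regression per
origin state on the expected transitions (IRLS to convergence), and the
mean first-hour posterior for the initial distribution in the M-step.
Emission variances are floored at 1e-8, convergence is Δlogℓ < 1e-8
(max 500 iterations), and the best of several seeded restarts (means
jittered around a median split; transition coefficients start at a
persistence-only configuration) is kept. States are relabelled afterwards
so μ_active > μ_rest; under a label swap the transition coefficients map
to the negated opposite rows, leaving the likelihood unchanged. Decoding
is Viterbi per segment. Each bat is modelled individually — every
bat-tower geometry is unique, and the per-bat series are short enough that
pooling assumptions would dominate the data.

Decoded states restricted to night hours are summarised by univariate
logistic regressions of P(active) on date, hours-since-sunset, wind speed
and temperature; covariates are centred for numerical stability (slopes
unchanged), and all-one-state or separated fits are flagged degenerate
rather than raised.

## Synthetic scenario generator

The generator defines the study conditions for all tests. It emulates a
fall season (Aug 15 – Oct 15) on a coastal plain with two north–south
water bodies whose opposite-shore towers sit ~35 km apart (wide enough
that a transit is unambiguous, narrower than the 50-km migration
threshold), ten shore towers plus inland scatter to the southwest, a
single collocated weather station, and a cohort of 40 tagged bats
(14 residents, 10 migrants, 12 bay-crossers, 4 long-distance returners —
the field cohort's behaviour mix at a desk-friendly scale). Tag lives are
uniform on 15–30 days, matching nanotag battery/retention spans.

* **Weather.** Temperature = seasonal linear decline (22 → 10 °C) +
  diurnal sinusoid (±4 °C, peak ~14:00 local) + AR(1) noise (φ = 0.8);
  wind speed = exponentiated AR(1) (median ~3 m/s); wind direction =
  wrapped random walk; pressure = AR(1) around 101.3 kPa plus sparse
  frontal steps; precipitation = sparse bursts; visibility = 16 km minus a
  precipitation-coupled reduction, clamped to [0, 16].
* **Bats.** Residents rest at a roost and forage within ~10 km; their
  hourly rest/active states follow the HMM truth below, with an extra pull
  toward activity of 0.15 logit units per °C above the season mean (so
  rest becomes more likely as temperature falls). Migrants depart after
  1–3 nights on a heading drawn near 230°, travelling ~25 km/h during
  night hours toward a far tower and continuing past it. Crossers are
  shore residents whose hourly probability of a bay transit is
  logit⁻¹(−6.0 − 0.35·hss − 0.30·wind + 0.12·temp) — signs and magnitudes
  follow the field estimates for over-water flight, with the intercept set
  so a crosser averages ~1.2 transits per 40 nights (the field rate);
  a transit flies to the opposite shore in two hours and the bat roosts
  there until the next trigger. Returners make one > 55 km excursion and
  come back. Truth labels record *realised* behaviour: a crosser that
  never transited is labelled a resident, since no classifier could
  distinguish them from detections.
* **Detections.** Detection probability is 1 within 6 km, linear to 0 at
  12 km (only the 12-km upper bound is externally given). Signal strength
  is 60 − 15·ln(d_km + 1) plus Gaussian noise with SD 1 at rest and 6 when
  active — the within-hour variance contrast that makes the HMM stage
  recoverable; each detected bat-hour emits a run of 4 + Poisson(3) pulses
  on one or two of three antennas, with occasional sub-threshold noise
  runs (length ≤ 3) and, for 10% of tags, a shed-transmitter tail: the
  bat's detections are truncated ~8–10 days before battery death and
  replaced by steady pings at the last tower.

What the generator does **not** emulate: realistic coastline geometry and
coastal-vs-inland route structure, detection-probability anisotropy from
antenna bearings, variable pulse intervals, weather-station displacement
from towers (collocated here), torpor physiology beyond the rest/active
dichotomy, and inter-annual structure. Passing tests therefore demonstrate
the pipeline's correctness and statistical calibration under a
well-specified data-generating process, not robustness to the many ways
field data violate it.

## Validation studies and problem sizes

Two seeded recovery studies calibrate the statistical core; their problem
sizes were chosen to mirror the field study's scale:

* **Selection model**: 100 replicates of 30 crossers over 40-night
  windows; crossing hours drawn from the true propensity model
  (~30–40 used points per replicate, 10× availability), the model fit with
  the true covariate subset. Each slope's ±2 SE interval covers its true
  value in ≈ 93–98% of replicates — the nominal Wald rate. Coverage is
  assessed per coefficient; requiring all slopes simultaneously would have
  a nominal joint rate below 90% for any correct model with ≥ 2 slopes.
* **Activity HMM**: 50 replicates of 600-hour series from the emission/
  transition truth above, fit with 3 restarts. Emission means and SDs land
  within 15% relative error and Viterbi decoding is ≥ 85% accurate in
  every replicate at the default separation (~3 pooled SDs between state
  means).

The forward likelihood and Viterbi path are checked against exhaustive
enumeration over all 2^T paths for T ≤ 10 (|Δlogℓ| < 1e-8), EM iterations
are asserted non-decreasing to 1e-9, and the pinned-variance mixed logit
matches an independent IRLS oracle to 1e-6. The end-to-end pipeline runs a
40-bat season in well under a minute on one CPU; the full 1,024-model
dredge on a ~400-row table takes ~2–3 minutes.

## Known limitations

* The tag-drop SD tolerance and the 6-km full-detection radius are
  package choices for quantities the field protocol leaves to judgement.
* Availability is temporal only (no spatial availability), and the
  pooled-availability alternative is not implemented; sampling is per
  contributing tag, proportional to its used count.
* Quasi-separated dredge subsets carry bounded, not maximum-likelihood,
  coefficients; their AICc values are conservative.
* The HMM assumes Gaussian emissions for a non-negative index (values are
  clipped at zero in the direct simulator); a truncated or Gamma emission
  would be more faithful at very low activity levels.
* Hour bins are UTC clock hours (identical partition to whole-hour local
  standard time at the study longitudes); sub-hourly behaviour is noise by
  construction.
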