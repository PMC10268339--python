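# batmove

Automated-radiotelemetry movement analysis for migratory bats: detection
cleaning, rule-based behaviour classification, a use-availability model of
over-water flight, and covariate-transition hidden Markov models of
site-resident activity.

## What it is for

Coded-VHF receiver networks (Motus-style) log timestamped tag detections —
tag id, time, tower, antenna, signal strength, run length — as tagged
animals pass within range. `batmove` turns such detection tables, together
with tag deployments, tower locations, and hourly weather, into the three
standard products of a coastal fall-migration telemetry study:

1. **Movement categories.** After removing noise runs (length ≤ 3),
   implausibly distant detections (> 1,000 km from the release point and
   from neighbouring detections), and shed-transmitter tails (≥ 7 days of
   steady signal), each bat is classified: *migrant* (a one-way hop
   > 50 km), *site resident* (> 1 night of detections within 12 km of
   release), both, or *long-distance return* (a > 50 km round trip). The
   cohort summary reports counts, the circular mean and range of travel
   bearings, and minimum residency times (days from tagging to the last
   local detection).

2. **Over-water flight.** Same-night detections on opposite shores of a
   named water body are crossing events. Each event's midpoint hour is a
   *used* point; ten *available* hours per used point are drawn from the
   tag's first 40 days at liberty. The binary response is modelled as a
   logistic GLMM — `logit P(used) = x'β + u_tag`, `u_tag ~ N(0, σ²)` —
   with the random intercept integrated by adaptive Gauss–Hermite
   quadrature. An all-subsets AICc dredge ranks every additive combination
   of the ten atmospheric covariates (2¹⁰ = 1,024 models, hours-since-
   sunset held in all of them), and marginal-effect curves with 95%
   intervals are produced for the competitive (ΔAICc < 2) models.

3. **Resident activity.** For bats in long residency (> 20 days, gaps
   ≤ 2 days), the hour-by-hour SD of antenna-scaled signal strength is an
   activity index: steady signal means a roosting bat, fluctuating signal
   a flying one. A per-bat two-state Gaussian HMM whose transition
   probabilities are logistic in sine/cosine of hours-since-sunset is fit
   by EM, decoded with Viterbi, and the decoded night-hour states are
   regressed against date, hours-since-sunset, wind speed and temperature.

A seeded synthetic-scenario generator (towers flanking two bays, weather
with diurnal and frontal structure, bats drawn from resident / migrant /
bay-crosser / returner archetypes with ground-truth labels) makes the
whole pipeline testable without any field download. `docs/methods.md`
documents every model, rule, default, and the generator's scope.

## Worked example

```python
from batmove import synth, telemetry, behavior, overwater

sim = synth.simulate_scenario(synth.ScenarioConfig(seed=1))
kept = telemetry.filter_run_length(sim["detections"])
tracks = [telemetry.trim_tag_drop(telemetry.filter_implausible(t, sim["towers"]))
          for t in telemetry.build_tracks(kept, sim["deployments"])]
summaries = [behavior.classify_track(t, sim["towers"]) for t in tracks]
cohort = behavior.summarize_cohort(summaries)
events = overwater.detect_crossings(tracks, sim["towers"])

print(f"detected {cohort.n_detected}/{cohort.n_tagged} bats; "
      f"{cohort.n_migrant} migrants, {cohort.n_resident} residents, "
      f"{cohort.n_return} long-distance returns")
print(f"mean travel bearing {cohort.mean_bearing_deg:.0f} deg "
      f"(min {cohort.min_bearing_deg:.0f}, max {cohort.max_bearing_deg:.0f})")
print(f"mean minimum residency {cohort.residency_mean_days:.1f} days "
      f"(q05 {cohort.residency_q05:.0f}, q95 {cohort.residency_q95:.0f})")
print(f"{len(events)} over-water crossing events by "
      f"{len({e.tag_id for e in events})} bats")
```

prints

```
detected 40/40 bats; 10 migrants, 40 residents, 4 long-distance returns
mean travel bearing 228 deg (min 207, max 251)
mean minimum residency 14.8 days (q05 1, q95 28)
15 over-water crossing events by 13 bats
```

All 40 simulated bats are detected and every archetype is recovered by the
rules: the 10 migrant-archetype bats classify as migrants on a
southwesterly mean bearing (the heading the generator draws near 230°),
the 4 returners as long-distance returns, and the bay transits the
generator's crossing-propensity model produced appear as same-night
crossing events. Residency times average about two weeks because many
tags outlive the bats' local stays.

The same pipeline runs from a shell:

```bash
batmove run-all --seed 1 --out-dir out/      # simulate -> clean -> classify -> rsf -> hmm -> report
batmove rsf --out-dir out/ --ratio 10        # re-run one stage on existing files
```

Every stage reads and writes plain CSV/JSON interfaces (`detections.csv`,
`behavior_summary.csv`, `crossings.csv`, `use_avail.csv`,
`rsf_models.csv`, `activity_series.csv`, `decoded_states.csv`, …) in the
output directory, plus a manifest auditing each filter's record counts.

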