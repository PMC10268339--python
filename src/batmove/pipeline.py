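"""End-to-end orchestration: simulate -> clean -> classify -> rsf -> hmm -> report.

Each stage reads and writes the package's CSV/JSON interfaces inside one
output directory, so stages can be re-run individually and audited.  All
randomness flows from one root seed through named substreams; the run
manifest records the configuration, per-filter record counts and stage
timings (the manifest is the only output that is not byte-reproducible,
because it carries wall-clock timings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, behavior, overwater, synth, telemetry

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "batmove_out"
    # stage toggles
    run_simulate: bool = True
    run_clean: bool = True
    run_classify: bool = True
    run_rsf: bool = True
    run_hmm: bool = True
    run_report: bool = True
    # cleaning thresholds
    min_run: int = 4
    implausible_km: float = 1000.0
    steady_days: float = 7.0
    # classification thresholds
    migration_km: float = 50.0
    residency_km: float = 12.0
    return_radius_km: float = 12.0
    # rsf
    ratio: int = 10
    horizon_days: float = 40.0
    rsf_candidate_vars: tuple = overwater.CANDIDATE_VARS
    rsf_always_in: tuple = overwater.ALWAYS_IN
    # hmm
    hmm_min_days: int = 20
    hmm_max_gap_days: int = 2
    hmm_restarts: int = 10
    hmm_max_bats: int = 4
    scenario: synth.ScenarioConfig | None = None

    def __post_init__(self) -> None:
        for name in ("min_run", "implausible_km", "migration_km", "residency_km", "ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scenario is None:
            self.scenario = synth.ScenarioConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scen = raw.pop("scenario", None)
        cfg = cls(**raw)
        if scen is not None:
            cfg.scenario = synth.ScenarioConfig(seed=cfg.seed, **scen)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["study_start"] = str(d["scenario"]["study_start"])
        d["scenario"]["study_end"] = str(d["scenario"]["study_end"])
        return d


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write every interface file.

    Returns the manifest (also written to ``manifest.json``): configuration
    hash, seed, stage timings, and record counts in/out of every cleaning
    filter so the cascade is auditable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "counts": {},
    }

    towers = weather = deployments = detections = None
    truth = None

    if config.run_simulate:
        t0 = time.perf_counter()
        scen = config.scenario
        sim = synth.simulate_scenario(scen)
        towers, weather = sim["towers"], sim["weather"]
        deployments, detections, truth = sim["deployments"], sim["detections"], sim["truth"]
        telemetry.write_towers(towers, out / "towers.csv")
        telemetry.write_deployments(deployments, out / "deployments.csv")
        telemetry.write_detections(detections, out / "detections.csv")
        synth.write_weather(weather, out / "weather.csv")
        synth.write_truth(truth, out / "truth.csv")
        manifest["stages"]["simulate"] = time.perf_counter() - t0
        manifest["counts"]["simulated_detections"] = len(detections)
    else:
        towers = telemetry.read_towers(out / "towers.csv")
        deployments = telemetry.read_deployments(out / "deployments.csv")
        detections = telemetry.read_detections(out / "detections.csv")
        weather = synth.read_weather(out / "weather.csv")

    tracks = None
    if config.run_clean:
        t0 = time.perf_counter()
        n0 = len(detections)
        kept = telemetry.filter_run_length(detections, min_run=config.min_run)
        manifest["counts"]["after_run_length"] = len(kept)
        tracks = telemetry.build_tracks(kept, deployments)
        tracks = [
            telemetry.filter_implausible(tr, towers, max_km=config.implausible_km)
            for tr in tracks
        ]
        manifest["counts"]["after_implausible"] = sum(len(t.detections) for t in tracks)
        tracks = [
            telemetry.trim_tag_drop(tr, steady_days=config.steady_days) for tr in tracks
        ]
        manifest["counts"]["after_tag_drop_trim"] = sum(len(t.detections) for t in tracks)
        cleaned = [d for tr in tracks for d in tr.detections]
        telemetry.write_detections(cleaned, out / "cleaned_detections.csv")
        logger.info(
            "cleaning cascade: %d -> %d -> %d -> %d detections",
            n0,
            manifest["counts"]["after_run_length"],
            manifest["counts"]["after_implausible"],
            manifest["counts"]["after_tag_drop_trim"],
        )
        manifest["stages"]["clean"] = time.perf_counter() - t0
    elif config.run_classify or config.run_rsf or config.run_hmm:
        cleaned = telemetry.read_detections(out / "cleaned_detections.csv")
        tracks = telemetry.build_tracks(cleaned, deployments)

    if config.run_classify:
        t0 = time.perf_counter()
        summaries = [behavior.classify_track(tr, towers) for tr in tracks]
        behavior.write_behavior_summaries(summaries, out / "behavior_summary.csv")
        cohort = behavior.summarize_cohort(summaries)
        behavior.write_cohort_summary(cohort, out / "cohort_summary.json")
        manifest["counts"]["n_detected"] = cohort.n_detected
        manifest["counts"]["n_migrant"] = cohort.n_migrant
        manifest["counts"]["n_resident"] = cohort.n_resident
        manifest["counts"]["n_return"] = cohort.n_return
        manifest["stages"]["classify"] = time.perf_counter() - t0

    if config.run_rsf:
        t0 = time.perf_counter()
        events = overwater.detect_crossings(tracks, towers)
        overwater.write_crossings(events, out / "crossings.csv")
        manifest["counts"]["n_crossing_events"] = len(events)
        contributing = {e.tag_id for e in events}
        if len(events) >= 5 and len(contributing) >= 2:
            avail = overwater.sample_available(
                events,
                deployments,
                ratio=config.ratio,
                horizon_days=config.horizon_days,
                seed=config.seed + 101,
            )
            rows = overwater.build_use_avail(events, avail)
            rows = overwater.attach_covariates(rows, weather, deployments)
            ua = rows.copy()
            ua["timestamp"] = ua["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
            ua.to_csv(out / "use_avail.csv", index=False)
            dredge = overwater.dredge_aicc(
                rows, config.rsf_candidate_vars, config.rsf_always_in
            )
            overwater.dredge_table(dredge).to_csv(out / "rsf_models.csv", index=False)
            top = dredge.competitive[0] if dredge.competitive else None
            if top is not None:
                curves = []
                for var in top.variable_subset:
                    c = overwater.marginal_effects(top, rows, var)
                    c.insert(0, "variable", var)
                    curves.append(c)
                pd.concat(curves).to_csv(out / "marginal_effects.csv", index=False)
        else:
            logger.warning("rsf: too few crossing events (%d); model skipped", len(events))
        manifest["stages"]["rsf"] = time.perf_counter() - t0

    if config.run_hmm:
        t0 = time.perf_counter()
        residents = activity.select_residents(
            tracks, towers, min_days=config.hmm_min_days, max_gap_days=config.hmm_max_gap_days
        )
        residents.sort(
            key=lambda tr: behavior.classify_residency(tr, towers)[1] or 0, reverse=True
        )
        residents = residents[: config.hmm_max_bats]
        manifest["counts"]["n_hmm_bats"] = len(residents)
        ser_rows, dec_rows, trend_rows = [], [], []
        for tr in residents:
            series = activity.build_activity_series(tr, towers, weather)
            if len(series) < 48:
                continue
            fit = activity.fit_hmm(
                series, restarts=config.hmm_restarts, seed=config.seed + 202
            )
            (out / f"hmm_fit_{tr.tag_id}.json").write_text(fit.to_json())
            sdf = series.covariates.copy()
            sdf.insert(0, "tag_id", tr.tag_id)
            sdf.insert(1, "hour", series.hours.strftime("%Y-%m-%dT%H:%M:%SZ"))
            sdf.insert(2, "value", series.values)
            sdf["segment_id"] = series.segment_id
            ser_rows.append(sdf)
            dec_rows.append(
                pd.DataFrame(
                    {
                        "tag_id": tr.tag_id,
                        "hour": series.hours.strftime("%Y-%m-%dT%H:%M:%SZ"),
                        "state": np.where(fit.decoded_states == 1, "active", "rest"),
                    }
                )
            )
            trends = activity.state_condition_trends(fit.decoded_states, series.covariates)
            for v, tfit in trends.items():
                trend_rows.append(
                    {
                        "tag_id": tr.tag_id,
                        "variable": v,
                        "slope": tfit.slope,
                        "intercept": tfit.intercept,
                        "degenerate": tfit.degenerate,
                    }
                )
        if ser_rows:
            pd.concat(ser_rows).to_csv(out / "activity_series.csv", index=False)
            pd.concat(dec_rows).to_csv(out / "decoded_states.csv", index=False)
            pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)
        manifest["stages"]["hmm"] = time.perf_counter() - t0

    if config.run_report:
        t0 = time.perf_counter()
        report(out)
        manifest["stages"]["report"] = time.perf_counter() - t0

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def _kde_density(day_numbers: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE with Scott's plug-in bandwidth, normalised on the grid."""
    from scipy.stats import gaussian_kde

    if len(day_numbers) < 2 or np.std(day_numbers) == 0:
        return np.zeros_like(grid)
    dens = gaussian_kde(day_numbers)(grid)
    area = np.trapezoid(dens, grid)
    return dens / area if area > 0 else dens


def report(out_dir) -> Path:
    """Render the summary document and figure data from stage outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    lines = ["# Movement analysis report", ""]

    cohort = None
    if (out / "cohort_summary.json").exists():
        cohort = json.loads((out / "cohort_summary.json").read_text())
        lines += ["## Overall patterns", ""]
        lines += [
            f"- tagged: {cohort['n_tagged']}, detected: {cohort['n_detected']}",
            f"- migrants: {cohort['n_migrant']}, residents: {cohort['n_resident']}, "
            f"both: {cohort['n_both']}, long-distance returns: {cohort['n_return']}",
        ]
        if cohort["mean_bearing_deg"] is not None:
            lines.append(
                f"- mean bearing {cohort['mean_bearing_deg']:.0f} deg "
                f"(min {cohort['min_bearing_deg']:.0f}, max {cohort['max_bearing_deg']:.0f})"
            )
        else:
            lines.append("- mean bearing: undefined (no migrants or zero resultant)")
        if cohort["residency_mean_days"] is not None:
            lines.append(
                f"- mean minimum residency {cohort['residency_mean_days']:.1f} days "
                f"(q05 {cohort['residency_q05']:.0f}, q95 {cohort['residency_q95']:.0f})"
            )
        lines.append("")

    if (out / "behavior_summary.csv").exists():
        beh = pd.read_csv(out / "behavior_summary.csv")
        bearings = beh["bearing_deg"].dropna().to_numpy()
        edges = np.arange(0, 361, 20)
        hist, _ = np.histogram(bearings, bins=edges)
        pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": hist}).to_csv(
            out / "bearing_hist.csv", index=False
        )
        if len(bearings):
            fig = plt.figure(figsize=(5, 5))
            ax = fig.add_subplot(projection="polar")
            ax.set_theta_zero_location("N")
            ax.set_theta_direction(-1)
            ax.bar(np.radians(edges[:-1] + 10), hist, width=np.radians(20), alpha=0.6)
            ax.set_title("Migration bearings")
            fig.savefig(fig_dir / "bearings.png", dpi=110)
            plt.close(fig)

        # timing densities (day of year) for migration and crossing events
        mig_days = pd.to_datetime(
            beh.loc[beh["migrant"] == True, "last_detection_time"]  # noqa: E712
        ).dt.dayofyear.to_numpy()
        cross_days = np.array([])
        if (out / "crossings.csv").exists():
            cr = pd.read_csv(out / "crossings.csv")
            if len(cr):
                cross_days = pd.to_datetime(cr["night"]).dt.dayofyear.to_numpy()
        if len(mig_days) >= 2 or len(cross_days) >= 2:
            lo = min([d.min() for d in (mig_days, cross_days) if len(d)]) - 5
            hi = max([d.max() for d in (mig_days, cross_days) if len(d)]) + 5
            grid = np.linspace(lo, hi, 200)
            dens = pd.DataFrame({"day_of_year": grid})
            dens["migration_density"] = _kde_density(mig_days, grid)
            dens["crossing_density"] = _kde_density(cross_days, grid)
            dens.to_csv(out / "timing_density.csv", index=False)
            fig, ax = plt.subplots(figsize=(7, 4))
            ax.plot(grid, dens["migration_density"], label="migration")
            ax.plot(grid, dens["crossing_density"], label="over-water crossing")
            ax.set_xlabel("day of year")
            ax.set_ylabel("density")
            ax.legend()
            fig.savefig(fig_dir / "timing_density.png", dpi=110)
            plt.close(fig)

    if (out / "marginal_effects.csv").exists():
        me = pd.read_csv(out / "marginal_effects.csv")
        lines += ["## Over-water flight model", ""]
        nvars = me["variable"].nunique()
        lines.append(f"- marginal effects for {nvars} top-model covariates (Figures)")
        lines.append("")
        fig, axes = plt.subplots(
            1, nvars, figsize=(3 * nvars, 3), squeeze=False, sharey=True
        )
        for ax, (var, sub) in zip(axes.ravel(), me.groupby("variable")):
            ax.fill_between(sub["value"], sub["lower95"], sub["upper95"], alpha=0.3)
            ax.plot(sub["value"], sub["prob"], color="k")
            ax.set_xlabel(var)
        axes[0, 0].set_ylabel("relative probability")
        fig.tight_layout()
        fig.savefig(fig_dir / "marginal_effects.png", dpi=110)
        plt.close(fig)

    if (out / "trends.csv").exists():
        tr = pd.read_csv(out / "trends.csv")
        lines += ["## Site-residency activity", ""]
        for var, sub in tr.groupby("variable"):
            ok = sub[~sub["degenerate"]]
            if len(ok):
                lines.append(
                    f"- {var}: mean logistic slope {ok['slope'].mean():+.3f} "
                    f"across {len(ok)} bats"
                )
            else:
                lines.append(f"- {var}: degenerate (single decoded state)")
        lines.append("")

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
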