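"""Rule-based movement classification and cohort summaries.

Cleaned tracks are classified with the field-standard distance rules:

* **migration** — detection at one tower followed by detection at another
  tower more than 50 km away, with no later detection returning within a
  "nearby" radius of the origin;
* **long-distance return** — the >50 km excursion exists but the bat is
  later re-detected near the origin (a round trip);
* **site residency** — detections at towers within 12 km of the release
  point spanning more than one night; the minimum residency time is the
  whole days from tagging to the last local detection.

Cohort summaries report counts per category, the circular (vector) mean and
range of migratory bearings, and the mean and 0.05/0.95 quantiles of
minimum residency times.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .telemetry import Tower, Track, haversine_km, initial_bearing_deg, night_id

__all__ = [
    "BehaviorSummary",
    "CohortSummary",
    "classify_migration",
    "classify_residency",
    "travel_bearing",
    "classify_track",
    "summarize_cohort",
    "write_behavior_summaries",
    "write_cohort_summary",
]

MIGRATION_KM = 50.0
RESIDENCY_KM = 12.0
#: "return to the original or nearby detection location": nearby reuses the
#: residency radius, since the rule text leaves it unquantified.
RETURN_RADIUS_KM = 12.0


@dataclass
class BehaviorSummary:
    tag_id: str
    detected: bool
    resident: bool
    migrant: bool
    long_distance_return: bool
    bearing_deg: float | None
    min_residency_days: int | None
    last_tower_id: str | None
    last_detection_time: datetime | None


@dataclass
class CohortSummary:
    n_tagged: int
    n_detected: int
    n_migrant: int
    n_resident: int
    n_both: int
    n_return: int
    mean_bearing_deg: float | None
    min_bearing_deg: float | None
    max_bearing_deg: float | None
    bearing_undefined: bool
    residency_mean_days: float | None
    residency_q05: float | None
    residency_q95: float | None


def _tower_index(towers: Iterable[Tower]) -> dict[str, Tower]:
    return {t.tower_id: t for t in towers}


def classify_migration(
    track: Track,
    towers: Iterable[Tower],
    threshold_km: float = MIGRATION_KM,
    return_radius_km: float = RETURN_RADIUS_KM,
) -> str:
    """Classify a track as ``"migrant"``, ``"long_distance_return"`` or ``"neither"``.

    The release point counts as the initial location, so a bat whose only
    detections are at a single far tower is still a migrant.  A hop is a
    later location more than ``threshold_km`` from an earlier one; a hop is
    "returned" when some detection after it comes back within
    ``return_radius_km`` of the hop's origin.  Documented round trips take
    priority: if any hop is returned the track is a long-distance return
    (otherwise the return leg itself would masquerade as a one-way
    migration); a track with only unreturned hops is a migrant.
    """
    if not track.detections:
        raise ValueError(f"classify_migration: track {track.tag_id} has no detections")
    idx = _tower_index(towers)
    dep = track.deployment
    for d in track.detections:
        if d.tower_id not in idx:
            raise KeyError(f"classify_migration: unknown tower_id {d.tower_id!r}")

    # Work over unique locations (release point + towers) with their
    # occurrence indices in the detection sequence; distances depend only on
    # location identity, so this is equivalent to the all-pairs scan but
    # scales with the number of towers, not detections.
    coords: dict[str, tuple[float, float]] = {"__release__": (dep.release_lat, dep.release_lon)}
    seq_ids = ["__release__"] + [d.tower_id for d in track.detections]
    for d in track.detections:
        t = idx[d.tower_id]
        coords.setdefault(d.tower_id, (t.lat, t.lon))
    occ: dict[str, list[int]] = {}
    for pos, lid in enumerate(seq_ids):
        occ.setdefault(lid, []).append(pos)
    ids = list(occ)
    dmat = {
        (a, b): haversine_km(*coords[a], *coords[b]) for a in ids for b in ids
    }

    found_excursion = False
    found_return = False
    for a in ids:
        first_a = occ[a][0]
        for b in ids:
            if dmat[a, b] <= threshold_km:
                continue
            pos = int(np.searchsorted(occ[b], first_a + 1))
            if pos == len(occ[b]):
                continue  # b never observed after a
            j = occ[b][pos]
            found_excursion = True
            if any(
                dmat[a, c] <= return_radius_km and occ[c][-1] > j for c in ids
            ):
                found_return = True
    if found_return:
        return "long_distance_return"
    return "migrant" if found_excursion else "neither"


def classify_residency(
    track: Track, towers: Iterable[Tower], radius_km: float = RESIDENCY_KM
) -> tuple[bool, int | None]:
    """Residency flag and minimum residency time in whole days.

    A bat is a site resident when detections at towers closer than
    ``radius_km`` to the release point span more than one night.  The
    minimum residency time is the calendar-day difference between the
    tagging date and the last local detection date (a single-day resident
    would score 0).
    """
    idx = _tower_index(towers)
    dep = track.deployment
    local = [
        d
        for d in track.detections
        if d.tower_id in idx
        and haversine_km(idx[d.tower_id].lat, idx[d.tower_id].lon, dep.release_lat, dep.release_lon)
        < radius_km
    ]
    if not local:
        return False, None
    nights = {night_id(d.timestamp, dep.release_lat, dep.release_lon) for d in local}
    resident = len(nights) > 1
    last_date = max(d.timestamp.astimezone(timezone.utc).date() for d in local)
    days = (last_date - dep.release_time.astimezone(timezone.utc).date()).days
    return resident, (days if resident else None)


def travel_bearing(track: Track, towers: Iterable[Tower]) -> float:
    """Bearing from the release point to the last-detection tower (migrants).

    Raises when the track is not classified as a migrant, or when the last
    tower coincides with the release point.
    """
    if classify_migration(track, towers) != "migrant":
        raise ValueError(f"travel_bearing: track {track.tag_id} is not a migrant")
    idx = _tower_index(towers)
    dep = track.deployment
    last = track.detections[-1]
    t = idx[last.tower_id]
    return initial_bearing_deg(dep.release_lat, dep.release_lon, t.lat, t.lon)


def classify_track(track: Track, towers: Iterable[Tower]) -> BehaviorSummary:
    """Full per-bat behaviour summary from a cleaned track."""
    if not track.detections:
        return BehaviorSummary(
            track.tag_id, False, False, False, False, None, None, None, None
        )
    migration = classify_migration(track, towers)
    resident, res_days = classify_residency(track, towers)
    migrant = migration == "migrant"
    bearing = travel_bearing(track, towers) if migrant else None
    last = track.detections[-1]
    return BehaviorSummary(
        tag_id=track.tag_id,
        detected=True,
        resident=resident,
        migrant=migrant,
        long_distance_return=migration == "long_distance_return",
        bearing_deg=bearing,
        min_residency_days=res_days,
        last_tower_id=last.tower_id,
        last_detection_time=last.timestamp,
    )


def circular_mean_deg(bearings: Sequence[float]) -> float:
    """Vector mean of angles in degrees; raises on a zero resultant."""
    ang = np.radians(np.asarray(bearings, dtype=float))
    x, y = np.mean(np.cos(ang)), np.mean(np.sin(ang))
    if math.hypot(x, y) < 1e-9:
        raise ValueError("circular mean undefined: zero resultant vector")
    deg = math.degrees(math.atan2(y, x)) % 360.0
    return 0.0 if deg >= 360.0 else deg


def summarize_cohort(summaries: Sequence[BehaviorSummary]) -> CohortSummary:
    """Aggregate per-bat summaries into cohort counts and statistics.

    The mean bearing is the circular mean over migrant bearings (flagged
    undefined on a zero resultant); min/max are plain order statistics on
    [0, 360).  Residency quantiles use linear interpolation.
    """
    if not summaries:
        raise ValueError("summarize_cohort: no summaries")
    bearings = [s.bearing_deg for s in summaries if s.bearing_deg is not None]
    residency = [s.min_residency_days for s in summaries if s.min_residency_days is not None]

    mean_b = None
    undefined = False
    if bearings:
        try:
            mean_b = circular_mean_deg(bearings)
        except ValueError:
            undefined = True

    return CohortSummary(
        n_tagged=len(summaries),
        n_detected=sum(s.detected for s in summaries),
        n_migrant=sum(s.migrant for s in summaries),
        n_resident=sum(s.resident for s in summaries),
        n_both=sum(s.migrant and s.resident for s in summaries),
        n_return=sum(s.long_distance_return for s in summaries),
        mean_bearing_deg=mean_b,
        min_bearing_deg=min(bearings) if bearings else None,
        max_bearing_deg=max(bearings) if bearings else None,
        bearing_undefined=undefined,
        residency_mean_days=float(np.mean(residency)) if residency else None,
        residency_q05=float(np.quantile(residency, 0.05)) if residency else None,
        residency_q95=float(np.quantile(residency, 0.95)) if residency else None,
    )


def write_behavior_summaries(summaries: Sequence[BehaviorSummary], path) -> None:
    rows = []
    for s in summaries:
        r = asdict(s)
        if s.last_detection_time is not None:
            r["last_detection_time"] = s.last_detection_time.astimezone(timezone.utc).strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            )
        rows.append(r)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cohort_summary(summary: CohortSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(summary), fh, indent=2)
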