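"""Phase classification and migration-event assembly.

Each fix of a cleaned track is assigned to exactly one contiguous phase:

* ``WINTERING`` / ``BREEDING`` / ``SUMMERING`` — residency periods,
* ``STOPOVER`` — a stationary period longer than 24 h en route,
* ``STATIONARY`` — a stationary period of at most 24 h en route,
* ``TRAVELLING`` — directed movement with net displacement above 50 km.

Stationary periods are found as maximal runs of fixes staying within a
radius of the run's incremental centroid; runs whose separating movement
never exceeds the 50-km displacement threshold are merged (a 40-km
excursion and return does not split a residency). Migration events are
then cut at residency phases: an event is complete when it is bounded by
residency at both ends, incomplete when the track dies en route.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import GeoPoint, gc_distance_km, great_circle_km
from .io import Track

WINTERING = "WINTERING"
TRAVELLING = "TRAVELLING"
STOPOVER = "STOPOVER"
STATIONARY = "STATIONARY"
BREEDING = "BREEDING"
SUMMERING = "SUMMERING"
RESIDENCY_LABELS = frozenset({WINTERING, BREEDING, SUMMERING})

SPRING = "SPRING"
AUTUMN = "AUTUMN"

__all__ = [
    "Phase", "MigrationEvent", "SegmentationParams",
    "detect_stationary_runs", "classify_phases", "split_migration_events",
    "segment_track", "phase_table",
    "WINTERING", "TRAVELLING", "STOPOVER", "STATIONARY", "BREEDING",
    "SUMMERING", "SPRING", "AUTUMN", "RESIDENCY_LABELS",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the phase classifier (km, hours, days, degrees)."""

    stationary_radius_km: float = 30.0
    min_displacement_km: float = 50.0
    stopover_min_h: float = 24.0
    breeding_lat_deg: float = 60.0
    breeding_window: tuple[str, str] = ("05-15", "08-15")
    breeding_min_d: float = 7.0
    summering_min_d: float = 30.0
    forward_progress_frac: float = 0.8

    def __post_init__(self) -> None:
        for name in ("stationary_radius_km", "min_displacement_km",
                     "stopover_min_h", "summering_min_d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Phase:
    """A labelled contiguous interval of a track (fix indices inclusive)."""

    label: str
    i0: int
    i1: int
    centroid: GeoPoint
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    arrival_estimated: bool = False
    departure_estimated: bool = False

    @property
    def duration_h(self) -> float:
        return (self.t_end - self.t_start).total_seconds() / 3600.0

    @property
    def n_fixes(self) -> int:
        return self.i1 - self.i0 + 1


@dataclass
class MigrationEvent:
    """One spring or autumn journey between residency phases."""

    bird_id: str
    season: str
    complete: bool
    phases: list[Phase]                    # transit phases only
    departure: pd.Timestamp
    arrival: pd.Timestamp
    origin_phase: Phase | None = None
    dest_phase: Phase | None = None
    departure_estimated: bool = False
    arrival_estimated: bool = False

    @property
    def i_dep(self) -> int:
        """Index of the last fix before departure (end of origin residency)."""
        return self.origin_phase.i1 if self.origin_phase else self.phases[0].i0

    @property
    def i_arr(self) -> int:
        """Index of the first fix after arrival (start of destination residency)."""
        return self.dest_phase.i0 if self.dest_phase else self.phases[-1].i1

    @property
    def year(self) -> int:
        return int(self.departure.year)


def detect_stationary_runs(track: Track, radius_km: float = 30.0) -> list[tuple[int, int]]:
    """Maximal runs of consecutive fixes within ``radius_km`` of the run's
    incremental centroid; only runs of >= 2 fixes count (a lone fix is transit).

    Returns inclusive (start, end) index pairs.
    """
    lon, lat = track.lons, track.lats
    n = len(lon)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        c_lon, c_lat, m = lon[i], lat[i], 1
        j = i + 1
        while j < n:
            d = float(gc_distance_km(c_lon, c_lat, lon[j], lat[j]))
            if d > radius_km:
                break
            # incremental centroid update (planar mean adequate at this radius)
            c_lon = (c_lon * m + lon[j]) / (m + 1)
            c_lat = (c_lat * m + lat[j]) / (m + 1)
            m += 1
            j += 1
        if m >= 2:
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    return runs


def _run_centroid(track: Track, i0: int, i1: int) -> GeoPoint:
    return GeoPoint(float(np.mean(track.lons[i0:i1 + 1])),
                    float(np.mean(track.lats[i0:i1 + 1])))


def _merge_close_runs(track: Track, runs: list[tuple[int, int]],
                      min_displacement_km: float) -> list[tuple[int, int]]:
    """Merge consecutive runs whose centroids are within the displacement
    threshold: the intervening movement is sub-threshold excursion, not travel."""
    if not runs:
        return runs
    merged = [runs[0]]
    for i0, i1 in runs[1:]:
        p_prev = _run_centroid(track, *merged[-1])
        p_this = _run_centroid(track, i0, i1)
        if great_circle_km(p_prev, p_this) <= min_displacement_km:
            merged[-1] = (merged[-1][0], i1)  # absorbs the gap fixes too
        else:
            merged.append((i0, i1))
    return merged


def _overlaps_window(t0: pd.Timestamp, t1: pd.Timestamp, window: tuple[str, str]) -> bool:
    """Does [t0, t1] overlap the month-day window in any covered year?"""
    for year in range(t0.year, t1.year + 1):
        w0 = pd.Timestamp(f"{year}-{window[0]}", tz="UTC")
        w1 = pd.Timestamp(f"{year}-{window[1]}", tz="UTC")
        if t0 <= w1 and t1 >= w0:
            return True
    return False


def classify_phases(track: Track, runs: list[tuple[int, int]] | None = None,
                    params: SegmentationParams = SegmentationParams()) -> list[Phase]:
    """Label every fix with a phase; returns contiguous phases covering the track.

    A track with no stationary run lasting the stopover minimum anywhere is
    classified all-TRAVELLING (no residency anchor to cut journeys at).
    """
    if runs is None:
        runs = detect_stationary_runs(track, params.stationary_radius_km)
    runs = _merge_close_runs(track, runs, params.min_displacement_km)
    times = track.times
    n = len(track)

    def make_phase(label: str, i0: int, i1: int) -> Phase:
        return Phase(label, i0, i1, _run_centroid(track, i0, i1),
                     times[i0], times[i1])

    durations = [(times[i1] - times[i0]).total_seconds() / 3600.0 for i0, i1 in runs]
    if not runs or max(durations) < params.stopover_min_h:
        return [make_phase(TRAVELLING, 0, n - 1)] if n else []

    labels = [None] * len(runs)
    centroids = [_run_centroid(track, i0, i1) for i0, i1 in runs]

    def is_breeding_candidate(k: int) -> bool:
        return (track.deployment.age_class == "adult"
                and centroids[k].lat >= params.breeding_lat_deg
                and durations[k] / 24.0 >= params.breeding_min_d
                and _overlaps_window(times[runs[k][0]], times[runs[k][1]],
                                     params.breeding_window))

    # wintering anchor: the run containing the deployment fix — unless that
    # run is itself a breeding candidate (Arctic-tagged track) — else the
    # longest run overlapping Nov-Feb
    dep_idx = next((k for k, (i0, i1) in enumerate(runs) if i0 == 0), None)
    if dep_idx is not None and is_breeding_candidate(dep_idx):
        dep_idx = None
    if dep_idx is None:
        winterish = [k for k, (i0, i1) in enumerate(runs)
                     if (times[i0].month in (11, 12, 1, 2)
                         or times[i1].month in (11, 12, 1, 2))
                     and not is_breeding_candidate(k)]
        dep_idx = max(winterish, key=lambda k: durations[k]) if winterish else None
    if dep_idx is not None:
        anchor = centroids[dep_idx]
        for k, c in enumerate(centroids):
            if great_circle_km(anchor, c) <= params.min_displacement_km:
                labels[k] = WINTERING

    # breeding: longest unlabelled high-latitude run overlapping the Arctic
    # summer window (adults only)
    breeding_idx = None
    if track.deployment.age_class == "adult":
        cands = [k for k in range(len(runs))
                 if labels[k] is None
                 and centroids[k].lat >= params.breeding_lat_deg
                 and durations[k] / 24.0 >= params.breeding_min_d
                 and _overlaps_window(times[runs[k][0]], times[runs[k][1]],
                                      params.breeding_window)]
        if cands:
            breeding_idx = max(cands, key=lambda k: durations[k])
            labels[breeding_idx] = BREEDING

    # summering: only for tracks that never reach the breeding grounds —
    # a prolonged mid-latitude run inside the same window
    if breeding_idx is None:
        cands = [k for k in range(len(runs))
                 if labels[k] is None
                 and durations[k] / 24.0 > params.summering_min_d
                 and _overlaps_window(times[runs[k][0]], times[runs[k][1]],
                                      params.breeding_window)]
        if cands:
            labels[max(cands, key=lambda k: durations[k])] = SUMMERING

    for k in range(len(runs)):
        if labels[k] is None:
            labels[k] = STOPOVER if durations[k] > params.stopover_min_h else STATIONARY

    phases: list[Phase] = []
    cursor = 0
    for k, (i0, i1) in enumerate(runs):
        if i0 > cursor:
            phases.append(make_phase(TRAVELLING, cursor, i0 - 1))
        phases.append(make_phase(labels[k], i0, i1))
        cursor = i1 + 1
    if cursor < n:
        phases.append(make_phase(TRAVELLING, cursor, n - 1))
    return phases


def split_migration_events(phases: list[Phase], bird_id: str = "") -> list[MigrationEvent]:
    """Cut phases into residency-to-residency migration events.

    An event is complete iff bounded by residency phases at both ends; a
    track lost en route yields a final event with ``complete=False``.
    Season follows the net displacement: poleward -> SPRING, equatorward
    -> AUTUMN, ties broken by departure month (Jan-Jun -> SPRING).
    """
    events: list[MigrationEvent] = []
    res_idx = [i for i, p in enumerate(phases) if p.label in RESIDENCY_LABELS]
    if not res_idx:
        return events

    bounds: list[tuple[int | None, int | None]] = []
    for a, b in zip(res_idx[:-1], res_idx[1:]):
        if b > a + 1:
            bounds.append((a, b))
    if res_idx[-1] < len(phases) - 1:           # transmitter died en route
        bounds.append((res_idx[-1], None))
    if res_idx[0] > 0:                          # track begins mid-journey
        bounds.insert(0, (None, res_idx[0]))

    for a, b in bounds:
        block = phases[(a + 1 if a is not None else 0):(b if b is not None else len(phases))]
        if not block:
            continue
        origin = phases[a] if a is not None else None
        dest = phases[b] if b is not None else None
        departure = origin.t_end if origin else block[0].t_start
        arrival = dest.t_start if dest else block[-1].t_end
        o_lat = origin.centroid.lat if origin else block[0].centroid.lat
        d_lat = dest.centroid.lat if dest else block[-1].centroid.lat
        if abs(d_lat - o_lat) > 1e-9:
            season = SPRING if d_lat > o_lat else AUTUMN
        else:
            season = SPRING if departure.month <= 6 else AUTUMN
        events.append(MigrationEvent(
            bird_id=bird_id, season=season,
            complete=(origin is not None and dest is not None),
            phases=list(block), departure=departure, arrival=arrival,
            origin_phase=origin, dest_phase=dest))
    return events


def segment_track(track: Track,
                  params: SegmentationParams = SegmentationParams()
                  ) -> tuple[list[Phase], list[MigrationEvent]]:
    """Convenience wrapper: stationary runs -> phases -> migration events."""
    phases = classify_phases(track, params=params)
    events = split_migration_events(phases, bird_id=track.bird_id)
    return phases, events


def phase_table(tracks_phases: dict[str, list[Phase]]) -> pd.DataFrame:
    """Flatten per-bird phase lists into the phase-table CSV layout."""
    rows = []
    for bird_id, phases in tracks_phases.items():
        for p in phases:
            rows.append({
                "bird_id": bird_id, "label": p.label,
                "t_start": p.t_start, "t_end": p.t_end,
                "centroid_lon": p.centroid.lon, "centroid_lat": p.centroid.lat,
                "n_fixes": p.n_fixes, "duration_h": p.duration_h,
                "arrival_estimated": p.arrival_estimated,
                "departure_estimated": p.departure_estimated,
            })
    return pd.DataFrame(rows)
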