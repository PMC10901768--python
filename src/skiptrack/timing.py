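"""Arrival/departure interpolation and per-journey migration metrics.

Sparse sampling makes the first fix at a stop a late bound on the true
arrival. Arrival is therefore back-extrapolated as the timestamp of the
last travelling fix plus the time needed to cover the remaining distance
at that travelling bout's mean speed; departure symmetrically uses the
following bout. Whenever the bounding fixes straddle a gap of 24 h or
more, no estimation is attempted and the dependent durations are flagged
invalid and excluded, which keeps badly-sampled transitions out of the
summary statistics.

Migration duration is days between departure and arrival; migration
speed is total distance flown (the great-circle fix chain from departure
to arrival) divided by that duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import gc_distance_km
from .io import Track
from .segmentation import (MigrationEvent, Phase, STATIONARY, STOPOVER,
                           TRAVELLING)

__all__ = [
    "StopoverVisit", "MigrationMetrics", "estimate_boundary_time",
    "day_of_year", "extract_visits", "migration_metrics", "metrics_table",
]


@dataclass
class StopoverVisit:
    """One visit to a stopover (or sub-24 h stationary) location."""

    bird_id: str
    phase: Phase
    t_arrive: pd.Timestamp
    t_depart: pd.Timestamp
    arrive_estimated: bool
    depart_estimated: bool
    duration_valid: bool
    season: str = ""
    site_id: int | None = None

    @property
    def duration_d(self) -> float:
        return (self.t_depart - self.t_arrive).total_seconds() / 86400.0

    @property
    def centroid(self):
        return self.phase.centroid

    @property
    def is_stopover(self) -> bool:
        return self.phase.label == STOPOVER


@dataclass
class MigrationMetrics:
    """Per-journey summary, one row of the migration-parameters table."""

    bird_id: str
    season: str
    complete: bool
    departure_doy: int | None
    arrival_doy: int | None
    duration_d: float | None
    distance_km: float | None
    speed_kmd: float | None
    n_stopovers: int
    n_stationary: int
    mean_stopover_d: float | None
    mean_stationary_d: float | None
    total_stopover_d: float | None


def day_of_year(date) -> int:
    """Days elapsed since 1 January of the same year, with 1 Jan -> 1."""
    ts = pd.Timestamp(date)
    return int(ts.dayofyear)


def estimate_boundary_time(t_travel_fix: pd.Timestamp, t_stop_fix: pd.Timestamp,
                           distance_km: float, bout_speed_kmh: float,
                           direction: str, max_gap_h: float = 24.0
                           ) -> tuple[pd.Timestamp, bool]:
    """Extrapolated arrival ('in') or departure ('out') instant at a stop.

    Returns (instant, estimated_flag). If the bounding fixes are
    ``max_gap_h`` or more apart, or the bout speed is unusable, the
    observed stop-fix time is returned unestimated; the caller must then
    mark dependent durations invalid. The estimate is clamped into the
    bounding-fix interval should the extrapolation overshoot.
    """
    gap_h = abs((t_stop_fix - t_travel_fix).total_seconds()) / 3600.0
    if gap_h >= max_gap_h or not np.isfinite(bout_speed_kmh) or bout_speed_kmh <= 0:
        return t_stop_fix, False
    travel_h = distance_km / bout_speed_kmh
    if direction == "in":      # arrival: last travelling fix + time to cover the gap
        est = t_travel_fix + pd.Timedelta(hours=travel_h)
        lo, hi = t_travel_fix, t_stop_fix
    elif direction == "out":   # departure: first travelling fix - time to cover the gap
        est = t_travel_fix - pd.Timedelta(hours=travel_h)
        lo, hi = t_stop_fix, t_travel_fix
    else:
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    return min(max(est, lo), hi), True


def _bout_speed_kmh(track: Track, phase: Phase) -> float:
    """Mean speed over a travelling bout: path length / elapsed time."""
    i0, i1 = phase.i0, phase.i1
    if i1 <= i0:
        return np.nan
    lon, lat = track.lons, track.lats
    d = float(np.sum(gc_distance_km(lon[i0:i1], lat[i0:i1], lon[i0 + 1:i1 + 1],
                                    lat[i0 + 1:i1 + 1])))
    h = (track.times[i1] - track.times[i0]).total_seconds() / 3600.0
    return d / h if h > 0 else np.nan


def extract_visits(track: Track, event: MigrationEvent,
                   max_gap_h: float = 24.0) -> list[StopoverVisit]:
    """Stopover and stationary visits of one event, with interpolated bounds."""
    lon, lat = track.lons, track.lats
    times = track.times
    visits = []
    for k, phase in enumerate(event.phases):
        if phase.label not in (STOPOVER, STATIONARY):
            continue
        prev = event.phases[k - 1] if k > 0 else None
        nxt = event.phases[k + 1] if k + 1 < len(event.phases) else None

        t_arr, arr_est = times[phase.i0], False
        if prev is not None and prev.label == TRAVELLING:
            j = prev.i1
            d = float(gc_distance_km(lon[j], lat[j], lon[phase.i0], lat[phase.i0]))
            t_arr, arr_est = estimate_boundary_time(
                times[j], times[phase.i0], d, _bout_speed_kmh(track, prev),
                "in", max_gap_h)
        arr_gap_ok = prev is None or prev.label != TRAVELLING or arr_est or \
            (times[phase.i0] - times[prev.i1]).total_seconds() / 3600.0 < max_gap_h

        t_dep, dep_est = times[phase.i1], False
        if nxt is not None and nxt.label == TRAVELLING:
            j = nxt.i0
            d = float(gc_distance_km(lon[phase.i1], lat[phase.i1], lon[j], lat[j]))
            t_dep, dep_est = estimate_boundary_time(
                times[j], times[phase.i1], d, _bout_speed_kmh(track, nxt),
                "out", max_gap_h)
        dep_gap_ok = nxt is None or nxt.label != TRAVELLING or dep_est or \
            (times[nxt.i0] - times[phase.i1]).total_seconds() / 3600.0 < max_gap_h

        phase.arrival_estimated = arr_est
        phase.departure_estimated = dep_est
        visits.append(StopoverVisit(
            bird_id=event.bird_id, phase=phase,
            t_arrive=t_arr, t_depart=t_dep,
            arrive_estimated=arr_est, depart_estimated=dep_est,
            duration_valid=bool(arr_gap_ok and dep_gap_ok),
            season=event.season))
    return visits


def migration_metrics(track: Track, event: MigrationEvent,
                      visits: list[StopoverVisit] | None = None,
                      max_gap_h: float = 24.0,
                      travelling_only_distance: bool = False) -> MigrationMetrics:
    """Metrics for one journey.

    Complete events report the full set (dates, duration, distance,
    speed); incomplete events report only stopover counts and durations,
    since departure/arrival are undefined mid-route.
    """
    if visits is None:
        visits = extract_visits(track, event, max_gap_h)
    stop = [v for v in visits if v.is_stopover]
    stat = [v for v in visits if not v.is_stopover]
    valid_stop = [v for v in stop if v.duration_valid]
    valid_stat = [v for v in stat if v.duration_valid]

    mean_stop = float(np.mean([v.duration_d for v in valid_stop])) if valid_stop else None
    mean_stat = float(np.mean([v.duration_d for v in valid_stat])) if valid_stat else None
    total_stop = float(np.sum([v.duration_d for v in valid_stop])) if valid_stop else None

    if not event.complete:
        return MigrationMetrics(
            bird_id=event.bird_id, season=event.season, complete=False,
            departure_doy=None, arrival_doy=None, duration_d=None,
            distance_km=None, speed_kmd=None,
            n_stopovers=len(stop), n_stationary=len(stat),
            mean_stopover_d=mean_stop, mean_stationary_d=mean_stat,
            total_stopover_d=total_stop)

    departure, arrival = event.departure, event.arrival
    # refine departure/arrival with the first/last travelling bout speeds
    lon, lat = track.lons, track.lats
    times = track.times
    first_travel = next((p for p in event.phases if p.label == TRAVELLING), None)
    last_travel = next((p for p in reversed(event.phases) if p.label == TRAVELLING), None)
    if first_travel is not None and event.origin_phase is not None:
        j0, j1 = event.origin_phase.i1, first_travel.i0
        d = float(gc_distance_km(lon[j1], lat[j1], lon[j0], lat[j0]))
        departure, dep_est = estimate_boundary_time(
            times[j1], times[j0], d, _bout_speed_kmh(track, first_travel),
            "out", max_gap_h)
        event.departure_estimated = dep_est
    if last_travel is not None and event.dest_phase is not None:
        j0, j1 = last_travel.i1, event.dest_phase.i0
        d = float(gc_distance_km(lon[j0], lat[j0], lon[j1], lat[j1]))
        arrival, arr_est = estimate_boundary_time(
            times[j0], times[j1], d, _bout_speed_kmh(track, last_travel),
            "in", max_gap_h)
        event.arrival_estimated = arr_est

    duration_d = (arrival - departure).total_seconds() / 86400.0
    if duration_d <= 0:
        raise ValueError(f"complete event with non-positive duration for {event.bird_id}")

    if travelling_only_distance:
        idx = np.concatenate([np.arange(p.i0, p.i1 + 1) for p in event.phases
                              if p.label == TRAVELLING]) if event.phases else np.array([], int)
        distance = float(np.sum(gc_distance_km(lon[idx[:-1]], lat[idx[:-1]],
                                               lon[idx[1:]], lat[idx[1:]]))) if len(idx) > 1 else 0.0
    else:
        a, b = event.i_dep, event.i_arr
        distance = float(np.sum(gc_distance_km(lon[a:b], lat[a:b],
                                               lon[a + 1:b + 1], lat[a + 1:b + 1])))
        # the journey runs residence-to-residence: run detection may absorb
        # the first/last in-flight fix into the bounding residency, so close
        # the chain back to the residency centroids
        oc = event.origin_phase.centroid
        dc = event.dest_phase.centroid
        distance += float(gc_distance_km(oc.lon, oc.lat, lon[a], lat[a]))
        distance += float(gc_distance_km(lon[b], lat[b], dc.lon, dc.lat))

    return MigrationMetrics(
        bird_id=event.bird_id, season=event.season, complete=True,
        departure_doy=day_of_year(departure), arrival_doy=day_of_year(arrival),
        duration_d=duration_d, distance_km=distance,
        speed_kmd=distance / duration_d,
        n_stopovers=len(stop), n_stationary=len(stat),
        mean_stopover_d=mean_stop, mean_stationary_d=mean_stat,
        total_stopover_d=total_stop)


def metrics_table(metrics: list[MigrationMetrics]) -> pd.DataFrame:
    """Journey metrics as a DataFrame mirroring the migration-parameters table."""
    return pd.DataFrame([m.__dict__ for m in metrics])
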