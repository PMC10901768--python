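"""Synthetic grey-plover journeys with known ground truth.

The generator builds a deterministic piecewise path — great-circle flight
legs flown at a fixed bout speed, parked dwells at waypoints — and then
samples it through a device model: a duty-cycled Argos PTT (10 h ON /
25 h OFF), a PinPoint GPS-Argos logger (3–5 GPS fixes a day with
occasional Doppler shadows and sub-10-min bursts) or an hourly GPS-UHF
logger. Positional scatter is measurement noise only, applied per fix
class, so the zero-noise limit reproduces the true path exactly and every
downstream stage can be scored against truth.

Default study conditions: wintering origins at the Bijagós archipelago
(Guinea-Bissau), the Tagus estuary (Portugal) and Moëze-Oléron (France);
breeding on the Yamal peninsula; 60 km/h flight bouts; spring departures
in early May; 2–6 stopovers of 1.1–20 days plus up to two sub-24 h
stationary stops per journey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import (EARTH_RADIUS_KM, GeoPoint, gc_interpolate, great_circle_km)
from .io import ARGOS_DOPPLER, GPS, Deployment, Track
from .segmentation import (AUTUMN, BREEDING, SPRING, STATIONARY, STOPOVER,
                           TRAVELLING, WINTERING)

__all__ = [
    "ORIGIN_ANCHORS", "BREEDING_ANCHORS", "DeviceModel", "JourneySpec",
    "ItineraryStop", "TruthStop", "TruthJourney", "GroundTruth", "TruthPath",
    "simulate_journey", "sample_device", "make_cohort", "make_journey_spec",
]

ORIGIN_ANCHORS = {
    "GB": GeoPoint(-15.8, 11.0),   # Bijagós archipelago, Guinea-Bissau
    "PT": GeoPoint(-9.05, 38.75),  # Tagus estuary, Portugal
    "FR": GeoPoint(-1.10, 45.90),  # Moëze-Oléron, France
}
BREEDING_ANCHORS = {
    "YAMAL": GeoPoint(70.0, 70.5),
    "EUROPEAN_RUSSIA": GeoPoint(50.0, 68.0),
    "TAIMYR": GeoPoint(95.0, 74.0),
}

#: Argos location-class 1-sigma error scales, km (CLS nominal accuracies)
ARGOS_CLASS_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 10.0, "B": 20.0,
                     "Z": 500.0}
#: PTT class mix (conditional on a non-Z fix)
ARGOS_CLASS_PROBS = {"3": 0.10, "2": 0.15, "1": 0.25, "0": 0.20, "A": 0.15, "B": 0.15}


@dataclass(frozen=True)
class DeviceModel:
    """Sampling schedule and error model of one tag type."""

    kind: str = "GPS_UHF"            # ARGOS_PTT | PINPOINT_GPS_ARGOS | GPS_UHF
    gps_sd_km: float = 0.03
    class_sd_km: dict = field(default_factory=lambda: dict(ARGOS_CLASS_SD_KM))
    class_probs: dict = field(default_factory=lambda: dict(ARGOS_CLASS_PROBS))
    z_frac: float = 0.02
    on_hours: float = 10.0
    off_hours: float = 25.0
    ptt_mean_interval_h: float = 1.5
    pinpoint_fixes_per_day: tuple[int, int] = (3, 5)
    pinpoint_doppler_per_day: float = 0.5
    pinpoint_burst_per_day: float = 0.1
    noise_scale: float = 1.0         # 0 -> noise-free sampling

    def zero_noise(self) -> "DeviceModel":
        return replace(self, noise_scale=0.0, z_frac=0.0)


@dataclass(frozen=True)
class ItineraryStop:
    """One dwell of the itinerary: where, how long, and its true phase label."""

    point: GeoPoint
    dwell_d: float
    label: str                        # WINTERING/STOPOVER/STATIONARY/BREEDING/...

    def __post_init__(self) -> None:
        if not self.dwell_d > 0:
            raise ValueError("dwell days must be positive")


@dataclass(frozen=True)
class JourneySpec:
    """A full itinerary for one bird: residencies, stops, and flight speed."""

    bird_id: str
    origin: str                       # GB | PT | FR
    itinerary: tuple[ItineraryStop, ...]
    start_time: pd.Timestamp
    bout_speed_kmh: float = 60.0

    def __post_init__(self) -> None:
        if len(self.itinerary) < 2:
            raise ValueError("itinerary needs at least two dwells")
        for a, b in zip(self.itinerary[:-1], self.itinerary[1:]):
            if great_circle_km(a.point, b.point) <= 50.0:
                raise ValueError("consecutive itinerary points must be >50 km apart")


@dataclass
class TruthStop:
    point: GeoPoint
    t_arrive: pd.Timestamp
    t_depart: pd.Timestamp
    label: str

    @property
    def dwell_d(self) -> float:
        return (self.t_depart - self.t_arrive).total_seconds() / 86400.0


@dataclass
class TruthJourney:
    """True parameters of one residency-to-residency journey."""

    season: str
    departure: pd.Timestamp
    arrival: pd.Timestamp
    distance_km: float
    stops: list[TruthStop]

    @property
    def duration_d(self) -> float:
        return (self.arrival - self.departure).total_seconds() / 86400.0

    @property
    def n_stopovers(self) -> int:
        return sum(1 for s in self.stops if s.label == STOPOVER)

    @property
    def n_stationary(self) -> int:
        return sum(1 for s in self.stops if s.label == STATIONARY)

    @property
    def speed_kmd(self) -> float:
        return self.distance_km / self.duration_d


@dataclass
class GroundTruth:
    """Everything the generator knows: the path segments and journey truths."""

    spec: JourneySpec
    segments: list[tuple[pd.Timestamp, pd.Timestamp, str, GeoPoint | None]]
    journeys: list[TruthJourney]
    fix_labels: np.ndarray | None = None   # filled by sample_device

    def label_at(self, t: pd.Timestamp) -> str:
        for t0, t1, label, _ in self.segments:
            if t0 <= t < t1:
                return label
        return self.segments[-1][2]

    @property
    def t_start(self) -> pd.Timestamp:
        return self.segments[0][0]

    @property
    def t_end(self) -> pd.Timestamp:
        return self.segments[-1][1]


class TruthPath:
    """Continuous position lookup over the piecewise itinerary path."""

    def __init__(self, truth: GroundTruth):
        self.truth = truth

    def position_at(self, t: pd.Timestamp) -> GeoPoint:
        segs = self.truth.segments
        if t <= segs[0][0]:
            return segs[0][3]
        for k, (t0, t1, label, pt) in enumerate(segs):
            if t0 <= t <= t1:
                if pt is not None:          # dwell: parked at the point
                    return pt
                a = segs[k - 1][3]
                b = segs[k + 1][3]
                frac = (t - t0).total_seconds() / max((t1 - t0).total_seconds(), 1e-9)
                lon, lat = gc_interpolate(a, b, [frac])[0]
                return GeoPoint(float(lon), float(lat))
        return segs[-1][3]


def simulate_journey(spec: JourneySpec, seed: int = 0) -> tuple[TruthPath, GroundTruth]:
    """Lay the itinerary out in time: dwells at the given points joined by
    great-circle flight legs at the bout speed. Deterministic under seed
    (the seed is reserved for stochastic path extensions; the default path
    itself is fully determined by the spec)."""
    segments = []
    t = spec.start_time
    for k, stop in enumerate(spec.itinerary):
        if k > 0:
            prev = spec.itinerary[k - 1]
            leg_km = great_circle_km(prev.point, stop.point)
            leg_h = leg_km / spec.bout_speed_kmh
            t1 = t + pd.Timedelta(hours=leg_h)
            segments.append((t, t1, TRAVELLING, None))
            t = t1
        t1 = t + pd.Timedelta(days=stop.dwell_d)
        segments.append((t, t1, stop.label, stop.point))
        t = t1

    residency = {WINTERING, BREEDING, "SUMMERING"}
    journeys: list[TruthJourney] = []
    res_idx = [k for k, s in enumerate(spec.itinerary) if s.label in residency]
    for a, b in zip(res_idx[:-1], res_idx[1:]):
        mid = spec.itinerary[a + 1:b]
        dep_seg = segments[2 * a]           # dwell segments sit at even positions
        arr_seg = segments[2 * b]
        departure, arrival = dep_seg[1], arr_seg[0]
        dist = sum(great_circle_km(spec.itinerary[k].point, spec.itinerary[k + 1].point)
                   for k in range(a, b))
        stops = []
        for k in range(a + 1, b):
            seg = segments[2 * k]
            stops.append(TruthStop(spec.itinerary[k].point, seg[0], seg[1],
                                   spec.itinerary[k].label))
        o_lat = spec.itinerary[a].point.lat
        d_lat = spec.itinerary[b].point.lat
        season = SPRING if d_lat > o_lat else AUTUMN
        journeys.append(TruthJourney(season, departure, arrival, dist, stops))

    truth = GroundTruth(spec, segments, journeys)
    return TruthPath(truth), truth


# ---------------------------------------------------------------------------
# device sampling


def _sample_times(model: DeviceModel, t0: pd.Timestamp, t1: pd.Timestamp,
                  rng: np.random.Generator) -> list[pd.Timestamp]:
    if model.kind == "GPS_UHF":
        start = t0.ceil("h")
        return list(pd.date_range(start, t1, freq="h"))
    if model.kind == "ARGOS_PTT":
        cycle_h = model.on_hours + model.off_hours
        phase = float(rng.uniform(0, cycle_h))
        times = []
        t = t0 + pd.Timedelta(hours=phase % cycle_h)
        cycle_start = t0 + pd.Timedelta(hours=(phase % cycle_h) - cycle_h)
        while cycle_start < t1:
            on0, on1 = cycle_start, cycle_start + pd.Timedelta(hours=model.on_hours)
            t = on0 + pd.Timedelta(hours=float(rng.exponential(model.ptt_mean_interval_h)))
            while t < min(on1, t1):
                if t >= t0:
                    times.append(t)
                t = t + pd.Timedelta(hours=max(
                    float(rng.exponential(model.ptt_mean_interval_h)), 5.0 / 60.0))
            cycle_start = cycle_start + pd.Timedelta(hours=cycle_h)
        return times
    if model.kind == "PINPOINT_GPS_ARGOS":
        times = []
        day = t0.normalize()
        lo, hi = model.pinpoint_fixes_per_day
        while day < t1:
            n = int(rng.integers(lo, hi + 1))
            offs = np.sort(rng.uniform(0, 24, size=n))
            day_times = [day + pd.Timedelta(hours=float(h)) for h in offs]
            day_times = [t for t in day_times if t0 <= t < t1]
            times.extend((t, GPS) for t in day_times)
            if day_times and rng.uniform() < model.pinpoint_doppler_per_day:
                anchor = day_times[int(rng.integers(len(day_times)))]
                times.append((anchor + pd.Timedelta(minutes=float(rng.uniform(1, 30))), ARGOS_DOPPLER))
            if day_times and rng.uniform() < model.pinpoint_burst_per_day:
                anchor = day_times[int(rng.integers(len(day_times)))]
                for m in (2.0, 4.0):
                    times.append((anchor + pd.Timedelta(minutes=m), GPS))
            day = day + pd.Timedelta(days=1)
        return times
    raise ValueError(f"unknown device kind: {model.kind}")


def _perturb(point: GeoPoint, sd_km: float, rng: np.random.Generator) -> GeoPoint:
    if sd_km <= 0:
        return point
    dn, de = rng.normal(0.0, sd_km, size=2)
    dlat = dn / 111.32
    dlon = de / (111.32 * max(math.cos(math.radians(point.lat)), 1e-6))
    return GeoPoint(point.lon + dlon, min(max(point.lat + dlat, -90.0), 90.0))


def sample_device(path: TruthPath, model: DeviceModel, seed: int = 0,
                  deployment: Deployment | None = None) -> tuple[Track, GroundTruth]:
    """Sample the true path through a device schedule and error model."""
    truth = path.truth
    rng = np.random.default_rng(seed)
    raw = _sample_times(model, truth.t_start, truth.t_end, rng)
    if model.kind == "PINPOINT_GPS_ARGOS":
        entries = sorted(raw, key=lambda x: x[0])
    else:
        src = GPS if model.kind == "GPS_UHF" else ARGOS_DOPPLER
        entries = [(t, src) for t in sorted(raw)]

    classes = list(model.class_probs)
    probs = np.array([model.class_probs[c] for c in classes], dtype=float)
    probs /= probs.sum()

    rows, labels = [], []
    for t, src in entries:
        p = path.position_at(t)
        if src == GPS:
            cls, sd = "NONE", model.gps_sd_km
        else:
            if model.z_frac > 0 and rng.uniform() < model.z_frac:
                cls = "Z"
            else:
                cls = classes[int(rng.choice(len(classes), p=probs))]
            sd = model.class_sd_km[cls]
        q = _perturb(p, sd * model.noise_scale, rng)
        rows.append({"timestamp": t, "lon": q.lon, "lat": q.lat,
                     "source": src, "argos_class": cls,
                     "quality_sd_km": sd * model.noise_scale})
        labels.append(truth.label_at(t))

    dep = deployment or Deployment(tagging_site=truth.spec.origin,
                                   tag_model=model.kind)
    track = Track(truth.spec.bird_id, pd.DataFrame(rows), dep)
    truth.fix_labels = np.array(labels)
    return track, truth


# ---------------------------------------------------------------------------
# cohort generation


def _offset_point(p: GeoPoint, bearing_deg: float, dist_km: float) -> GeoPoint:
    """Destination point at a bearing and great-circle distance from p."""
    delta = dist_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    phi1, lam1 = math.radians(p.lat), math.radians(p.lon)
    phi2 = math.asin(math.sin(phi1) * math.cos(delta)
                     + math.cos(phi1) * math.sin(delta) * math.cos(theta))
    lam2 = lam1 + math.atan2(math.sin(theta) * math.sin(delta) * math.cos(phi1),
                             math.cos(delta) - math.sin(phi1) * math.sin(phi2))
    return GeoPoint(math.degrees(lam2), math.degrees(phi2))


def _route_stops(a: GeoPoint, b: GeoPoint, n_stop: int, n_stat: int,
                 dwell_range: tuple[float, float],
                 rng: np.random.Generator) -> list[ItineraryStop]:
    """Place stops along the a->b great circle with lateral scatter,
    keeping consecutive points >50 km apart."""
    n = n_stop + n_stat
    for _ in range(100):
        fracs = np.sort(rng.uniform(0.12, 0.92, size=n))
        if n < 2 or np.min(np.diff(fracs)) > 0.03:
            break
    pts = gc_interpolate(a, b, fracs)
    stops = []
    route_km = great_circle_km(a, b)
    is_stat = np.zeros(n, bool)
    if n_stat:
        is_stat[rng.choice(n, size=n_stat, replace=False)] = True
    for k in range(n):
        base = GeoPoint(float(pts[k, 0]), float(pts[k, 1]))
        off = _offset_point(base, float(rng.uniform(0, 360)), float(rng.uniform(0, 120)))
        if is_stat[k]:
            dwell = float(rng.uniform(0.2, 0.8))
            label = STATIONARY
        else:
            dwell = float(rng.uniform(*dwell_range))
            label = STOPOVER
        stops.append(ItineraryStop(off, dwell, label))
    # enforce >50 km separation (route scale makes collisions rare)
    pruned = []
    prev = a
    for s in stops:
        if great_circle_km(prev, s.point) > 50.0 and great_circle_km(s.point, b) > 50.0:
            pruned.append(s)
            prev = s.point
    return pruned


def make_journey_spec(bird_id: str, origin: str = "GB", seed: int = 0,
                      season: str = SPRING, year: int = 2022,
                      breeding_site: str = "YAMAL",
                      n_stopovers: int | None = None,
                      n_stationary: int | None = None,
                      dwell_range: tuple[float, float] = (1.1, 20.0),
                      pre_dwell_d: float = 20.0, post_dwell_d: float = 30.0,
                      bout_speed_kmh: float = 60.0,
                      annual: bool = False) -> JourneySpec:
    """Draw a plausible spring (or annual) itinerary for one bird."""
    rng = np.random.default_rng(seed)
    wpt = ORIGIN_ANCHORS[origin]
    bpt = BREEDING_ANCHORS[breeding_site]
    n_stop = int(n_stopovers if n_stopovers is not None else rng.integers(2, 7))
    n_stat = int(n_stationary if n_stationary is not None else rng.integers(0, 3))

    dep_doy = int(rng.integers(121, 136))      # early-to-mid May departures
    start = (pd.Timestamp(f"{year}-01-01", tz="UTC")
             + pd.Timedelta(days=dep_doy - 1) - pd.Timedelta(days=pre_dwell_d))

    itinerary = [ItineraryStop(wpt, pre_dwell_d, WINTERING)]
    itinerary += _route_stops(wpt, bpt, n_stop, n_stat, dwell_range, rng)
    itinerary.append(ItineraryStop(bpt, post_dwell_d, BREEDING))
    if annual:
        n_stop_a = int(rng.integers(2, 7))
        itinerary += _route_stops(bpt, wpt, n_stop_a, int(rng.integers(0, 3)),
                                  dwell_range, rng)
        itinerary.append(ItineraryStop(wpt, 60.0, WINTERING))
    return JourneySpec(bird_id=bird_id, origin=origin,
                       itinerary=tuple(itinerary), start_time=start,
                       bout_speed_kmh=bout_speed_kmh)


def make_cohort(n_birds: int, seed: int = 0,
                origin_mix: dict[str, float] | None = None,
                device: DeviceModel = DeviceModel("GPS_UHF"),
                annual: bool = False,
                dwell_range: tuple[float, float] = (1.1, 20.0),
                year: int = 2022) -> list[tuple[Track, GroundTruth]]:
    """A reproducible heterogeneous cohort of tagged journeys with truth."""
    if n_birds < 1:
        raise ValueError("need at least one bird")
    origin_mix = origin_mix or {"GB": 0.5, "PT": 0.25, "FR": 0.25}
    rng = np.random.default_rng(seed)
    origins = list(origin_mix)
    w = np.array([origin_mix[o] for o in origins], dtype=float)
    w /= w.sum()
    out = []
    for i in range(n_birds):
        origin = origins[int(rng.choice(len(origins), p=w))]
        breeding = "YAMAL" if rng.uniform() < 0.7 else "EUROPEAN_RUSSIA"
        sub = int(rng.integers(0, 2**31 - 1))
        spec = make_journey_spec(f"bird{i:03d}", origin=origin, seed=sub,
                                 season=SPRING, year=year,
                                 breeding_site=breeding,
                                 dwell_range=dwell_range, annual=annual)
        path, truth = simulate_journey(spec, seed=sub)
        track, truth = sample_device(path, device, seed=sub + 1)
        out.append((track, truth))
    return out
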