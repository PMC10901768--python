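"""Reading, fusing and thinning raw telemetry fix streams.

A :class:`Track` is a time-ordered table of fixes for one bird-deployment,
carried as a pandas DataFrame with the canonical columns

    timestamp (UTC), lon, lat, source, argos_class, quality_sd_km

The reader speaks the Movebank CSV dialect by default
(`individual-local-identifier`, `timestamp`, `location-long`,
`location-lat`, `sensor-type`, `argos:lc`) and any other dialect via a
column mapping.

Fusion policy for duplicate timestamps: GPS beats Doppler; two fixes from
the same system are resolved by the one minimising the cumulative
great-circle distance to the two temporal neighbours. Burst thinning
iteratively removes the later fix of any pair closer than the minimum gap
(10 min by default), preserving bout onsets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .geo import gc_distance_km

logger = logging.getLogger(__name__)

GPS = "GPS"
ARGOS_DOPPLER = "ARGOS_DOPPLER"
ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z", "NONE")

#: canonical Movebank column names -> internal names
MOVEBANK_DIALECT: Mapping[str, str] = {
    "individual-local-identifier": "bird_id",
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
    "sensor-type": "source",
    "argos:lc": "argos_class",
}

FIX_COLUMNS = ["timestamp", "lon", "lat", "source", "argos_class", "quality_sd_km"]

__all__ = [
    "GPS", "ARGOS_DOPPLER", "ARGOS_CLASSES", "MOVEBANK_DIALECT",
    "Deployment", "Track", "read_fixes", "write_fixes",
    "merge_sources", "thin_bursts", "track_to_geojson",
]


@dataclass(frozen=True)
class Deployment:
    """Tagging metadata for one bird-deployment."""

    tagging_site: str = "GB"        # GB | PT | FR
    age_class: str = "adult"        # juvenile | second_cy | adult
    tag_model: str = "GPS_UHF"      # ARGOS_PTT | PINPOINT_GPS_ARGOS | GPS_UHF


@dataclass
class Track:
    """Time-ordered fixes for one bird-deployment."""

    bird_id: str
    fixes: pd.DataFrame
    deployment: Deployment = field(default_factory=Deployment)

    def __post_init__(self) -> None:
        df = self.fixes
        missing = [c for c in FIX_COLUMNS if c not in df.columns]
        if "quality_sd_km" in missing:
            df = df.assign(quality_sd_km=np.nan)
            missing.remove("quality_sd_km")
        if missing:
            raise ValueError(f"track table missing columns: {missing}")
        df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
        self.fixes = df[FIX_COLUMNS]

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def lons(self) -> np.ndarray:
        return self.fixes["lon"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.fixes["lat"].to_numpy(dtype=float)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.fixes["timestamp"])

    def with_fixes(self, df: pd.DataFrame) -> "Track":
        return Track(self.bird_id, df.reset_index(drop=True), self.deployment)

    def step_distances_km(self) -> np.ndarray:
        """Great-circle distance between successive fixes (length n-1)."""
        lon, lat = self.lons, self.lats
        if len(lon) < 2:
            return np.zeros(0)
        return gc_distance_km(lon[:-1], lat[:-1], lon[1:], lat[1:])

    def step_hours(self) -> np.ndarray:
        t = self.times.asi8.astype(float) / 3.6e12
        return np.diff(t)


def _normalise_source(s: str) -> str:
    s = str(s).strip().lower()
    if "gps" in s:
        return GPS
    return ARGOS_DOPPLER


def read_fixes(path, dialect: Mapping[str, str] | None = None,
               deployments: Mapping[str, Deployment] | None = None) -> list[Track]:
    """Read a Movebank-style CSV into one Track per bird.

    Malformed rows (unparseable timestamp, out-of-range coordinates) are
    dropped with a counted warning; a missing required column raises.
    """
    dialect = dict(dialect or MOVEBANK_DIALECT)
    df = pd.read_csv(path)
    missing = [c for c in dialect if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV missing required columns: {missing}")
    df = df.rename(columns=dialect)

    n_raw = len(df)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ok = ts.notna() & lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} malformed rows of {n_raw}", stacklevel=2)
    df = df.loc[ok].copy()
    df["timestamp"] = ts[ok]
    df["lon"] = lon[ok]
    df["lat"] = lat[ok]
    df["source"] = df["source"].map(_normalise_source)
    if "argos_class" in df.columns:
        cls = df["argos_class"].astype(str).str.strip().str.upper()
        cls = cls.where(cls.isin(ARGOS_CLASSES), "NONE")
    else:
        cls = pd.Series("NONE", index=df.index)
    df["argos_class"] = np.where(df["source"] == GPS, "NONE", cls)
    if "quality_sd_km" not in df.columns:
        df["quality_sd_km"] = np.nan

    tracks = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        dep = (deployments or {}).get(str(bird_id), Deployment())
        tracks.append(Track(str(bird_id), grp[FIX_COLUMNS], dep))
    return tracks


def write_fixes(tracks: Iterable[Track], path) -> None:
    """Write tracks back out in the canonical Movebank dialect (round-trips with read_fixes)."""
    inv = {v: k for k, v in MOVEBANK_DIALECT.items()}
    frames = []
    for tr in tracks:
        df = tr.fixes.copy()
        df.insert(0, "bird_id", tr.bird_id)
        df["source"] = np.where(df["source"] == GPS, "gps", "argos-doppler-shift")
        frames.append(df.drop(columns=["quality_sd_km"]).rename(columns=inv))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, date_format="%Y-%m-%d %H:%M:%S")


def merge_sources(track: Track) -> Track:
    """Resolve duplicate timestamps: keep GPS over Doppler, else the fix
    minimising summed distance to the temporal neighbours.

    Idempotent; a track with unique timestamps passes through unchanged.
    """
    df = track.fixes
    if df["timestamp"].is_unique:
        return track

    # representative point per unique timestamp for neighbour geometry:
    # GPS fix if present, else first listed
    by_ts = []
    for ts, grp in df.groupby("timestamp", sort=True):
        gps = grp[grp["source"] == GPS]
        rep = gps.iloc[0] if len(gps) else grp.iloc[0]
        by_ts.append((ts, grp, rep))

    keep_rows = []
    for i, (ts, grp, _) in enumerate(by_ts):
        if len(grp) == 1:
            keep_rows.append(grp.iloc[0])
            continue
        gps = grp[grp["source"] == GPS]
        if len(gps) == 1:
            keep_rows.append(gps.iloc[0])
            continue
        cands = gps if len(gps) > 1 else grp
        neighbours = []
        if i > 0:
            neighbours.append(by_ts[i - 1][2])
        if i < len(by_ts) - 1:
            neighbours.append(by_ts[i + 1][2])
        if not neighbours:           # single-timestamp track: keep first listed
            keep_rows.append(cands.iloc[0])
            continue
        cost = np.zeros(len(cands))
        for nb in neighbours:
            cost += gc_distance_km(cands["lon"].to_numpy(), cands["lat"].to_numpy(),
                                   nb["lon"], nb["lat"])
        keep_rows.append(cands.iloc[int(np.argmin(cost))])  # argmin keeps first on tie

    out = pd.DataFrame(keep_rows).reset_index(drop=True)
    return track.with_fixes(out)


def thin_bursts(track: Track, min_gap: pd.Timedelta = pd.Timedelta(minutes=10)) -> Track:
    """Iteratively remove fixes until consecutive gaps are all >= min_gap.

    Scanning forward in time, the later fix of an offending pair is
    removed (bout onsets are preserved); the first fix is always kept.
    """
    df = track.fixes
    if len(df) < 2:
        return track
    t = df["timestamp"].to_numpy()
    keep = [0]
    for i in range(1, len(df)):
        if t[i] - t[keep[-1]] >= min_gap.to_numpy():
            keep.append(i)
    return track.with_fixes(df.iloc[keep])


def track_to_geojson(track: Track) -> dict:
    """Track as a GeoJSON LineString feature (for quick inspection in a viewer)."""
    coords = [[round(x, 6), round(y, 6)] for x, y in zip(track.lons, track.lats)]
    return {
        "type": "Feature",
        "properties": {"bird_id": track.bird_id,
                       "tagging_site": track.deployment.tagging_site,
                       "n_fixes": len(track)},
        "geometry": {"type": "LineString", "coordinates": coords},
    }
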