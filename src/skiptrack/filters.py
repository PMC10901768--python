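"""Track quality filtering: invalid-class removal, speed gating, median smoothing.

The canonical order, mirroring how raw Argos/GPS streams degrade, is

    drop_invalid_class -> merge_sources -> thin_bursts -> speed_filter -> median_smooth

and is applied by :func:`apply_quality_filters`, which also returns
per-stage removal counts for the QC report.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .geo import gc_distance_km
from .io import Track, merge_sources, thin_bursts

__all__ = [
    "drop_invalid_class", "speed_filter", "median_smooth",
    "apply_quality_filters", "QCReport", "audit_speeds",
]


@dataclass
class QCReport:
    """Per-stage fix removal counts for one track."""

    bird_id: str
    n_input: int
    removed_class_z: int = 0
    removed_duplicates: int = 0
    removed_bursts: int = 0
    removed_speed: int = 0
    n_output: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def drop_invalid_class(track: Track) -> Track:
    """Remove Argos class-Z (invalid location) fixes; all other classes kept."""
    df = track.fixes
    keep = df["argos_class"] != "Z"
    if keep.all():
        return track
    return track.with_fixes(df.loc[keep])


def speed_filter(track: Track, vmax_ms: float = 30.0) -> Track:
    """Iteratively remove fixes implying speeds above ``vmax_ms`` (m/s).

    A forward scan keeps a fix only if the speed from the last kept fix
    does not exceed the threshold — blame falls on the later fix, the
    outlier candidate. This single pass is equivalent to iterating
    "remove the later fix of the first offending pair" to a fixed point,
    so the output passes an exhaustive pairwise audit. Distinct fixes at
    identical timestamps are burst artefacts: later one removed with a
    warning.
    """
    if not vmax_ms > 0:
        raise ValueError(f"vmax must be positive, got {vmax_ms}")
    df = track.fixes
    if len(df) < 2:
        return track
    lon, lat = track.lons, track.lats
    t = track.times.asi8.astype(float) / 1e9  # seconds
    keep = [0]
    zero_gap = 0
    for i in range(1, len(df)):
        j = keep[-1]
        dt = t[i] - t[j]
        d_m = float(gc_distance_km(lon[j], lat[j], lon[i], lat[i])) * 1000.0
        if dt <= 0:
            zero_gap += 1
            continue
        if d_m / dt <= vmax_ms:
            keep.append(i)
    if zero_gap:
        warnings.warn(f"{zero_gap} zero-time-gap fixes removed as burst artefacts",
                      stacklevel=2)
    if len(keep) == len(df):
        return track
    return track.with_fixes(df.iloc[keep])


def audit_speeds(track: Track, vmax_ms: float = 30.0) -> int:
    """Exhaustive consecutive-pair audit; returns the number of violations."""
    d_km = track.step_distances_km()
    dt_h = track.step_hours()
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ms = np.where(dt_h > 0, d_km / dt_h / 3.6, np.inf)
    v_ms = np.where((dt_h <= 0) & (d_km == 0), 0.0, v_ms)
    return int(np.sum(v_ms > vmax_ms))


def median_smooth(track: Track, k: int = 3) -> Track:
    """Running coordinate-wise median of window k; first and last fixes unchanged.

    Longitudes are unwrapped around the antimeridian before smoothing so a
    track crossing 180° is not torn apart. Timestamps are untouched.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError(f"window width must be odd and >= 3, got {k}")
    df = track.fixes
    n = len(df)
    if n <= 2:
        return track
    lon = np.unwrap(track.lons, period=360.0)
    lat = track.lats.copy()
    half = k // 2
    new_lon = lon.copy()
    new_lat = lat.copy()
    for i in range(1, n - 1):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        new_lon[i] = np.median(lon[lo:hi])
        new_lat[i] = np.median(lat[lo:hi])
    out = df.copy()
    sm_lon = (new_lon + 180.0) % 360.0 - 180.0
    sm_lon[[0, -1]] = track.lons[[0, -1]]   # endpoints verbatim
    new_lat[[0, -1]] = track.lats[[0, -1]]
    out["lon"] = sm_lon
    out["lat"] = new_lat
    return track.with_fixes(out)


def apply_quality_filters(track: Track, vmax_ms: float = 30.0, median_k: int = 3,
                          min_gap_min: float = 10.0) -> tuple[Track, QCReport]:
    """Full cleaning pipeline in the canonical order, with a QC report."""
    qc = QCReport(bird_id=track.bird_id, n_input=len(track))
    t1 = drop_invalid_class(track)
    qc.removed_class_z = len(track) - len(t1)
    t2 = merge_sources(t1)
    qc.removed_duplicates = len(t1) - len(t2)
    t3 = thin_bursts(t2, pd.Timedelta(minutes=min_gap_min))
    qc.removed_bursts = len(t2) - len(t3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t4 = speed_filter(t3, vmax_ms=vmax_ms)
    qc.removed_speed = len(t3) - len(t4)
    t5 = median_smooth(t4, k=median_k) if len(t4) > 2 else t4
    qc.n_output = len(t5)
    return t5, qc
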