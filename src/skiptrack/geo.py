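"""Geodesic and projection primitives.

All distances are great-circle distances on a sphere of radius
``EARTH_RADIUS_KM`` (mean Earth radius). Planar work uses a spherical
Lambert azimuthal equal-area projection whose centre defaults to the
Wadden Sea (54°N, 8°E); coordinates come out in kilometres with the
centre at the origin, which makes square-grid binning trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "ProjectionSpec",
    "great_circle_km",
    "gc_distance_km",
    "project_equal_area",
    "grid_cell",
    "grid_cells",
    "gc_interpolate",
    "cross_track_distance_km",
    "point_to_segment_km",
]


def _normalise_lon(lon: float) -> float:
    """Wrap a longitude into [-180, 180] (180 maps to 180, -180 stays)."""
    lon = (lon + 180.0) % 360.0 - 180.0
    return lon


@dataclass(frozen=True)
class GeoPoint:
    """A longitude/latitude pair in decimal degrees (WGS-84 style, treated spherically)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError(f"non-finite coordinates: ({self.lon}, {self.lat})")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        object.__setattr__(self, "lon", _normalise_lon(float(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))


@dataclass(frozen=True)
class ProjectionSpec:
    """Spherical Lambert azimuthal equal-area projection centred at (center_lon, center_lat)."""

    center_lon: float = 8.0
    center_lat: float = 54.0

    def __post_init__(self) -> None:
        GeoPoint(self.center_lon, self.center_lat)  # validates ranges


def gc_distance_km(lon1, lat1, lon2, lat2):
    """Vectorised haversine great-circle distance in km.

    Accepts scalars or numpy arrays (broadcast); inputs in decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    if not (np.all(np.isfinite(lon1)) and np.all(np.isfinite(lat1))
            and np.all(np.isfinite(lon2)) and np.all(np.isfinite(lat2))):
        raise ValueError("non-finite coordinates passed to gc_distance_km")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, km."""
    return float(gc_distance_km(a.lon, a.lat, b.lon, b.lat))


def project_equal_area(points: Sequence[GeoPoint] | np.ndarray,
                       spec: ProjectionSpec = ProjectionSpec()) -> np.ndarray:
    """Forward Lambert azimuthal equal-area projection, returning (n, 2) planar km.

    The projection centre maps to (0, 0); x grows east, y grows north.
    Points antipodal to the centre sit on the projection singularity and
    are rejected.
    """
    if isinstance(points, GeoPoint):
        points = [points]
    if isinstance(points, np.ndarray):
        lon = points[:, 0].astype(float)
        lat = points[:, 1].astype(float)
    else:
        lon = np.array([p.lon for p in points], dtype=float)
        lat = np.array([p.lat for p in points], dtype=float)
    lam0, phi0 = math.radians(spec.center_lon), math.radians(spec.center_lat)
    lam, phi = np.radians(lon), np.radians(lat)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    denom = 1.0 + cos_c
    if np.any(denom < 1e-12):
        raise ValueError("point antipodal to projection center (singularity)")
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi)
                               - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return np.column_stack([x, y])


def grid_cell(xy: Sequence[float], cell_km: float) -> tuple[int, int]:
    """Half-open square-grid cell index for one planar point.

    Cell (i, j) covers [i*c, (i+1)*c) x [j*c, (j+1)*c), anchored at the
    projection origin.
    """
    if not cell_km > 0:
        raise ValueError(f"cell size must be positive, got {cell_km}")
    x, y = float(xy[0]), float(xy[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("non-finite projected coordinates")
    return (math.floor(x / cell_km), math.floor(y / cell_km))


def grid_cells(xy: np.ndarray, cell_km: float) -> np.ndarray:
    """Vectorised :func:`grid_cell` over an (n, 2) array; returns (n, 2) ints."""
    if not cell_km > 0:
        raise ValueError(f"cell size must be positive, got {cell_km}")
    return np.floor(np.asarray(xy, dtype=float) / cell_km).astype(int)


# --- great-circle path helpers (used by the site-usage corridor test and
#     the synthetic flight-leg generator) ---------------------------------

def gc_interpolate(a: GeoPoint, b: GeoPoint, fracs) -> np.ndarray:
    """Points along the great circle from a to b at fractions ``fracs`` of arc length.

    Returns an (n, 2) array of lon/lat degrees. Uses spherical linear
    interpolation, so sub-arc distances are additive along the path.
    """
    fracs = np.atleast_1d(np.asarray(fracs, dtype=float))
    v1 = _unit_vector(a)
    v2 = _unit_vector(b)
    omega = math.acos(float(np.clip(np.dot(v1, v2), -1.0, 1.0)))
    if omega < 1e-12:
        out = np.tile(v1, (len(fracs), 1))
    else:
        s = math.sin(omega)
        w1 = np.sin((1.0 - fracs) * omega) / s
        w2 = np.sin(fracs * omega) / s
        out = w1[:, None] * v1[None, :] + w2[:, None] * v2[None, :]
        out /= np.linalg.norm(out, axis=1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(out[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(out[:, 1], out[:, 0]))
    return np.column_stack([lon, lat])


def _unit_vector(p: GeoPoint) -> np.ndarray:
    lam, phi = math.radians(p.lon), math.radians(p.lat)
    return np.array([math.cos(phi) * math.cos(lam),
                     math.cos(phi) * math.sin(lam),
                     math.sin(phi)])


def cross_track_distance_km(a: GeoPoint, b: GeoPoint, p: GeoPoint) -> float:
    """Unsigned distance from p to the full great circle through a and b, km."""
    d13 = great_circle_km(a, p) / EARTH_RADIUS_KM
    theta13 = _initial_bearing_rad(a, p)
    theta12 = _initial_bearing_rad(a, b)
    xt = math.asin(math.sin(d13) * math.sin(theta13 - theta12))
    return abs(xt) * EARTH_RADIUS_KM


def point_to_segment_km(a: GeoPoint, b: GeoPoint, p: GeoPoint) -> float:
    """Distance from p to the great-circle *segment* a→b, km.

    Uses the cross-track distance when the along-track projection of p
    falls inside the segment, and the nearer endpoint distance otherwise.
    """
    seg = great_circle_km(a, b)
    if seg < 1e-9:
        return great_circle_km(a, p)
    d13 = great_circle_km(a, p) / EARTH_RADIUS_KM
    theta13 = _initial_bearing_rad(a, p)
    theta12 = _initial_bearing_rad(a, b)
    xt = math.asin(max(-1.0, min(1.0, math.sin(d13) * math.sin(theta13 - theta12))))
    cos_xt = math.cos(xt)
    if abs(cos_xt) < 1e-12:
        at = 0.0
    else:
        at = math.acos(max(-1.0, min(1.0, math.cos(d13) / cos_xt))) * EARTH_RADIUS_KM
    # along-track sign: behind a if the bearing difference exceeds 90°
    if math.cos(theta13 - theta12) < 0:
        at = -at
    if at < 0:
        return great_circle_km(a, p)
    if at > seg:
        return great_circle_km(b, p)
    return abs(xt) * EARTH_RADIUS_KM


def segments_min_distance_km(lon: np.ndarray, lat: np.ndarray,
                             p: GeoPoint) -> float:
    """Minimum distance from p to the polyline of great-circle segments
    through (lon, lat), km. Vectorised counterpart of
    :func:`point_to_segment_km` over all consecutive segments.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if len(lon) == 0:
        return math.inf
    if len(lon) == 1:
        return float(gc_distance_km(lon[0], lat[0], p.lon, p.lat))
    a_lon, a_lat = lon[:-1], lat[:-1]
    b_lon, b_lat = lon[1:], lat[1:]
    d_ap = gc_distance_km(a_lon, a_lat, p.lon, p.lat)
    d_bp = gc_distance_km(b_lon, b_lat, p.lon, p.lat)
    seg = gc_distance_km(a_lon, a_lat, b_lon, b_lat)

    th12 = _bearings_rad(a_lon, a_lat, b_lon, b_lat)
    th13 = _bearings_rad(a_lon, a_lat, np.full_like(a_lon, p.lon),
                         np.full_like(a_lat, p.lat))
    d13 = d_ap / EARTH_RADIUS_KM
    xt = np.arcsin(np.clip(np.sin(d13) * np.sin(th13 - th12), -1.0, 1.0))
    cos_xt = np.cos(xt)
    with np.errstate(invalid="ignore", divide="ignore"):
        at = np.arccos(np.clip(np.cos(d13) / np.where(np.abs(cos_xt) < 1e-12, 1.0, cos_xt),
                               -1.0, 1.0)) * EARTH_RADIUS_KM
    at = np.where(np.cos(th13 - th12) < 0, -at, at)
    inside = (at >= 0) & (at <= seg) & (seg > 1e-9)
    d = np.where(inside, np.abs(xt) * EARTH_RADIUS_KM, np.minimum(d_ap, d_bp))
    return float(np.min(d))


def _bearings_rad(lon1, lat1, lon2, lat2):
    lam1, phi1 = np.radians(lon1), np.radians(lat1)
    lam2, phi2 = np.radians(lon2), np.radians(lat2)
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.arctan2(y, x)


def _initial_bearing_rad(a: GeoPoint, b: GeoPoint) -> float:
    lam1, phi1 = math.radians(a.lon), math.radians(a.lat)
    lam2, phi2 = math.radians(b.lon), math.radians(b.lat)
    dlam = lam2 - lam1
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return math.atan2(y, x)
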