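"""Stopover-site clustering, usage, accumulation curves and grid summaries.

Visits are clustered into discrete sites by single-linkage agglomeration
on great-circle centroid distance, cut at 50 km — the separation scale at
which consecutive stops count as different sites. Site usage is the
proportion of bird trips stopping at a site among all trips whose path
passed within a corridor of it. Accumulation curves (specaccum-style,
"random" method) quantify how fast new sites appear as birds are added
in permuted order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from shapely.geometry import Point, shape, box

from .geo import (GeoPoint, ProjectionSpec, gc_distance_km,
                  great_circle_km, grid_cells, point_to_segment_km,
                  project_equal_area, segments_min_distance_km)
from .io import Track
from .segmentation import MigrationEvent
from .timing import StopoverVisit

__all__ = [
    "StopoverSite", "SiteUsage", "cluster_sites", "site_usage",
    "accumulation_curve", "regional_summary", "default_regions",
    "load_regions_geojson", "sites_table",
]

#: default region polygons (lon/lat boxes), ordered: first match wins.
#: Wadden Sea precedes its neighbours so the shared coast resolves to it.
_DEFAULT_REGION_BOXES = [
    ("WADDEN_SEA", (4.5, 52.8, 9.8, 56.0)),
    ("WEST_AFRICA", (-20.0, -5.0, 0.0, 31.0)),
    ("WESTERN_EUROPE", (-12.0, 31.0, 12.0, 52.8)),
    ("NORTH_EUROPE", (-5.0, 52.8, 32.0, 72.0)),
    ("EUROPEAN_RUSSIA", (32.0, 50.0, 60.0, 78.0)),
    ("SIBERIA", (60.0, 50.0, 130.0, 78.0)),
]


@dataclass
class StopoverSite:
    """A discrete stopover site: a cluster of visits with a shared centroid."""

    site_id: int
    centroid: GeoPoint
    visits: list[StopoverVisit]
    region: str = "UNASSIGNED"

    @property
    def n_uses(self) -> int:
        return len(self.visits)


@dataclass
class SiteUsage:
    """Stopping vs crossing trip counts for one site."""

    site_id: int
    trips_stopping: int
    trips_crossing: int

    @property
    def proportion(self) -> float:
        return self.trips_stopping / self.trips_crossing


def default_regions() -> dict[str, object]:
    """Editable default region polygons as shapely geometries (ordered dict)."""
    return {name: box(x0, y0, x1, y1) for name, (x0, y0, x1, y1) in _DEFAULT_REGION_BOXES}


def load_regions_geojson(path) -> dict[str, object]:
    """Load region polygons from a GeoJSON FeatureCollection with a 'name' property."""
    gj = json.loads(Path(path).read_text())
    return {f["properties"]["name"]: shape(f["geometry"]) for f in gj["features"]}


def cluster_sites(visits: list[StopoverVisit], link_km: float = 50.0) -> list[StopoverSite]:
    """Single-linkage clustering of visit centroids on great-circle distance,
    cut at ``link_km``; deterministic, site ids ordered by earliest visit.
    """
    if not visits:
        return []
    if len(visits) == 1:
        v = visits[0]
        v.site_id = 0
        return [StopoverSite(0, v.centroid, [v])]
    lon = np.array([v.centroid.lon for v in visits])
    lat = np.array([v.centroid.lat for v in visits])
    dmat = gc_distance_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(dmat, 0.0)
    Z = linkage(squareform(dmat, checks=False), method="single")
    raw = fcluster(Z, t=link_km, criterion="distance")

    # relabel clusters by earliest visit time for deterministic site ids
    first_time = {}
    for v, c in zip(visits, raw):
        t = v.t_arrive
        if c not in first_time or t < first_time[c]:
            first_time[c] = t
    order = sorted(first_time, key=lambda c: first_time[c])
    remap = {c: i for i, c in enumerate(order)}

    sites: dict[int, list[StopoverVisit]] = {}
    for v, c in zip(visits, raw):
        sid = remap[c]
        v.site_id = sid
        sites.setdefault(sid, []).append(v)
    out = []
    for sid in sorted(sites):
        members = sites[sid]
        cen = GeoPoint(float(np.mean([v.centroid.lon for v in members])),
                       float(np.mean([v.centroid.lat for v in members])))
        out.append(StopoverSite(sid, cen, members))
    return out


def assign_regions(sites: list[StopoverSite],
                   regions: dict[str, object] | None = None) -> None:
    """Tag each site with the first region polygon containing its centroid."""
    regions = regions or default_regions()
    for s in sites:
        pt = Point(s.centroid.lon, s.centroid.lat)
        s.region = next((name for name, poly in regions.items() if poly.intersects(pt)),
                        "UNASSIGNED")


def _trip_key(event: MigrationEvent) -> tuple:
    return (event.bird_id, event.season, event.departure.year)


def site_usage(sites: list[StopoverSite],
               trips: list[tuple[Track, MigrationEvent]],
               corridor_km: float = 50.0) -> list[SiteUsage]:
    """Stopping/crossing counts per site over a set of bird trips.

    A trip crosses a site when the great-circle path interpolated between
    its consecutive fixes passes within ``corridor_km`` of the site
    centroid; it stops there when one of its visits was assigned to the
    site. By construction every stop also crosses, so proportions live in
    (0, 1].
    """
    stopping: dict[int, set] = {s.site_id: set() for s in sites}
    for s in sites:
        for v in s.visits:
            stopping[s.site_id].add((v.bird_id, v.season, v.t_arrive.year))

    crossing: dict[int, set] = {s.site_id: set() for s in sites}
    for track, event in trips:
        key = _trip_key(event)
        a, b = event.i_dep, event.i_arr
        lon, lat = track.lons[a:b + 1], track.lats[a:b + 1]
        for s in sites:
            if key in crossing[s.site_id]:
                continue
            if segments_min_distance_km(lon, lat, s.centroid) <= corridor_km:
                crossing[s.site_id].add(key)

    out = []
    for s in sites:
        cross = crossing[s.site_id] | stopping[s.site_id]  # a stop implies a crossing
        n_stop, n_cross = len(stopping[s.site_id]), len(cross)
        assert n_cross >= n_stop >= 1, "site without stopping trips"
        out.append(SiteUsage(s.site_id, n_stop, n_cross))
    return out


def accumulation_curve(bird_site_sets: dict[str, set],
                       n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
    """Site-accumulation curve over permuted bird orders.

    For each of ``n_perm`` random orderings, counts cumulative distinct
    sites after adding each bird; returns a DataFrame with columns
    ``n_birds``, ``mean_sites``, ``sd_sites`` (sd is the ddof=1 standard
    deviation across permutations, as specaccum reports).
    """
    birds = sorted(bird_site_sets)
    if not birds:
        raise ValueError("need at least one bird")
    rng = np.random.default_rng(seed)
    n = len(birds)
    curves = np.zeros((n_perm, n), dtype=float)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen: set = set()
        for j, idx in enumerate(order):
            seen |= bird_site_sets[birds[idx]]
            curves[p, j] = len(seen)
    return pd.DataFrame({
        "n_birds": np.arange(1, n + 1),
        "mean_sites": curves.mean(axis=0),
        "sd_sites": curves.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n),
    })


def regional_summary(sites: list[StopoverSite],
                     trips: list[tuple[Track, MigrationEvent]] | None = None,
                     regions: dict[str, object] | None = None,
                     proj: ProjectionSpec = ProjectionSpec(),
                     grid_km: float = 300.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grid-cell and region summaries of stopover use, split by season.

    Returns ``(cells, region_table)``: per-cell distinct-individual counts
    on the equal-area grid, and per-region distinct-site counts with mean
    uses per site. A bird tracked in two years counts as two individuals.
    """
    assign_regions(sites, regions)
    rows = []
    for s in sites:
        xy = project_equal_area([s.centroid], proj)
        ci, cj = grid_cells(xy, grid_km)[0]
        for v in s.visits:
            rows.append({"site_id": s.site_id, "region": s.region,
                         "cell_i": int(ci), "cell_j": int(cj),
                         "season": v.season,
                         "individual": f"{v.bird_id}/{v.t_arrive.year}"})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(), pd.DataFrame()
    cells = (df.groupby(["season", "cell_i", "cell_j"])["individual"]
             .nunique().rename("n_individuals").reset_index())
    region_table = (df.groupby(["season", "region"])
                    .agg(n_sites=("site_id", "nunique"),
                         n_uses=("individual", "size"))
                    .reset_index())
    region_table["mean_uses_per_site"] = region_table["n_uses"] / region_table["n_sites"]
    return cells, region_table


def sites_table(sites: list[StopoverSite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_id": s.site_id, "lon": s.centroid.lon, "lat": s.centroid.lat,
        "n_uses": s.n_uses, "region": s.region,
    } for s in sites])
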