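import itertools

import numpy as np
import pandas as pd
import pytest

from skiptrack.filters import apply_quality_filters
from skiptrack.geo import GeoPoint, gc_distance_km
from skiptrack.network import (accumulation_curve, assign_regions,
                               cluster_sites, default_regions,
                               regional_summary, site_usage)
from skiptrack.segmentation import STOPOVER, segment_track
from skiptrack.timing import extract_visits
from skiptrack.simulate import DeviceModel, make_cohort


def make_visit(lon, lat, bird="b1", t="2022-05-01", season="SPRING"):
    """Minimal stand-in visit (synthetic) with just the fields clustering uses."""
    from skiptrack.segmentation import Phase
    from skiptrack.timing import StopoverVisit
    ts = pd.Timestamp(t, tz="UTC")
    ph = Phase(STOPOVER, 0, 0, GeoPoint(lon, lat), ts, ts + pd.Timedelta(days=2))
    return StopoverVisit(bird, ph, ts, ts + pd.Timedelta(days=2),
                         False, False, True, season=season)


def brute_force_single_linkage(points, link_km):
    """Oracle: iteratively merge the closest pair of clusters until > link_km."""
    clusters = [[i] for i in range(len(points))]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = min(float(gc_distance_km(points[i][0], points[i][1],
                                         points[j][0], points[j][1]))
                    for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        if best[0] > link_km:
            break
        d, a, b = best
        clusters[a] += clusters[b]
        del clusters[b]
    return sorted(sorted(c) for c in clusters)


class TestClusterSites:
    def test_visits_beyond_link_distance_stay_distinct(self):
        # ~60 km apart at 54N
        visits = [make_visit(8.0, 54.0), make_visit(8.0, 54.54)]
        assert len(cluster_sites(visits, 50.0)) == 2

    def test_visits_within_link_distance_merge(self):
        visits = [make_visit(8.0, 54.0), make_visit(8.0, 54.27)]  # ~30 km
        sites = cluster_sites(visits, 50.0)
        assert len(sites) == 1 and sites[0].n_uses == 2

    def test_single_visit_single_site(self):
        sites = cluster_sites([make_visit(0.0, 0.0)])
        assert len(sites) == 1 and sites[0].site_id == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        pts = [(float(lo), float(la)) for lo, la in
               zip(rng.uniform(-10, 10, 15), rng.uniform(40, 60, 15))]
        visits = [make_visit(lo, la, bird=f"b{i}") for i, (lo, la) in enumerate(pts)]
        sites = cluster_sites(visits, 50.0)
        got = sorted(sorted(visits.index(v) for v in s.visits) for s in sites)
        assert got == brute_force_single_linkage(pts, 50.0)

    def test_site_count_invariant_to_visit_order(self):
        rng = np.random.default_rng(13)
        visits = [make_visit(float(lo), float(la), bird=f"b{i}")
                  for i, (lo, la) in enumerate(zip(rng.uniform(-5, 5, 12),
                                                   rng.uniform(40, 55, 12)))]
        n1 = len(cluster_sites(list(visits), 50.0))
        n2 = len(cluster_sites(list(reversed(visits)), 50.0))
        assert n1 == n2

    def test_every_visit_in_exactly_one_site(self):
        visits = [make_visit(float(l), 50.0, bird=f"b{i}")
                  for i, l in enumerate(np.linspace(0, 8, 9))]
        sites = cluster_sites(visits, 50.0)
        assert sum(s.n_uses for s in sites) == len(visits)


class TestAccumulationCurve:
    def test_single_bird(self):
        curve = accumulation_curve({"b1": {1, 2, 3, 4}}, n_perm=10, seed=0)
        assert list(curve["mean_sites"]) == [4.0]

    def test_identical_sets_flat(self):
        sets = {b: {1, 2, 3} for b in "abc"}
        curve = accumulation_curve(sets, n_perm=20, seed=0)
        assert np.allclose(curve["mean_sites"], 3.0)
        assert np.allclose(curve["sd_sites"], 0.0)

    def test_disjoint_sets_match_exhaustive_average(self):
        sets = {"a": {1}, "b": {2}, "c": {3}}
        curve = accumulation_curve(sets, n_perm=100, seed=1)
        # all 6 orders give cumulative counts 1,2,3 exactly
        assert np.allclose(curve["mean_sites"], [1.0, 2.0, 3.0])

    def test_overlapping_sets_match_enumeration_oracle(self):
        sets = {"a": {1, 2}, "b": {2, 3}, "c": {4}}
        birds = list(sets)
        totals = np.zeros(3)
        for order in itertools.permutations(range(3)):
            seen = set()
            for j, k in enumerate(order):
                seen |= sets[birds[k]]
                totals[j] += len(seen)
        oracle = totals / 6
        curve = accumulation_curve(sets, n_perm=2000, seed=3)
        assert np.allclose(curve["mean_sites"], oracle, atol=0.1)
        assert curve["mean_sites"].iloc[-1] == 4.0

    def test_monotone_and_ends_at_total(self):
        rng = np.random.default_rng(5)
        sets = {f"b{i}": set(rng.integers(0, 30, rng.integers(1, 8)).tolist())
                for i in range(10)}
        curve = accumulation_curve(sets, n_perm=50, seed=9)
        assert (np.diff(curve["mean_sites"]) >= -1e-12).all()
        assert curve["mean_sites"].iloc[-1] == len(set().union(*sets.values()))


@pytest.fixture(scope="module")
def cohort_pipeline():
    cohort = make_cohort(10, seed=21, device=DeviceModel("GPS_UHF").zero_noise())
    visits, trips = [], []
    for track, _ in cohort:
        clean, _ = apply_quality_filters(track)
        _, events = segment_track(clean)
        for ev in events:
            vs = extract_visits(clean, ev)
            visits.extend(v for v in vs if v.is_stopover)
            trips.append((clean, ev))
    sites = cluster_sites(visits, 50.0)
    return sites, trips, visits


class TestSiteUsage:
    def test_proportions_in_unit_interval(self, cohort_pipeline):
        sites, trips, _ = cohort_pipeline
        for u in site_usage(sites, trips):
            assert 0.0 < u.proportion <= 1.0
            assert u.trips_stopping <= u.trips_crossing

    def test_own_visits_always_cross(self, cohort_pipeline):
        sites, trips, _ = cohort_pipeline
        usages = {u.site_id: u for u in site_usage(sites, trips)}
        for s in sites:
            assert usages[s.site_id].trips_stopping >= 1

    def test_crossings_match_brute_force_on_subset(self, cohort_pipeline):
        from skiptrack.geo import point_to_segment_km
        sites, trips, _ = cohort_pipeline
        s = sites[0]
        usage = {u.site_id: u for u in site_usage(sites, trips)}[s.site_id]
        count = 0
        seen = set()
        for track, ev in trips:
            key = (ev.bird_id, ev.season, ev.departure.year)
            if key in seen:
                continue
            a, b = ev.i_dep, ev.i_arr
            lon, lat = track.lons[a:b + 1], track.lats[a:b + 1]
            hit = any(point_to_segment_km(GeoPoint(lon[i], lat[i]),
                                          GeoPoint(lon[i + 1], lat[i + 1]),
                                          s.centroid) <= 50.0
                      for i in range(len(lon) - 1))
            stopped = any(v.bird_id == ev.bird_id and v.site_id == s.site_id
                          for v in s.visits)
            if hit or stopped:
                count += 1
                seen.add(key)
        assert usage.trips_crossing == count

    def test_conservation_of_uses(self, cohort_pipeline):
        sites, _, visits = cohort_pipeline
        total_uses = sum(s.n_uses for s in sites)
        assert total_uses == len(visits)
        mean_uses = total_uses / len(sites)
        assert mean_uses * len(sites) == pytest.approx(total_uses)


class TestRegions:
    def test_wadden_sea_precedence(self):
        sites = [type("S", (), {})()]
        from skiptrack.network import StopoverSite
        s = StopoverSite(0, GeoPoint(8.5, 54.3), [])
        assign_regions([s])
        assert s.region == "WADDEN_SEA"

    def test_bird_in_two_years_counts_twice(self):
        visits = [make_visit(8.5, 54.3, bird="b1", t="2022-05-01"),
                  make_visit(8.5, 54.3, bird="b1", t="2023-05-02")]
        sites = cluster_sites(visits, 50.0)
        cells, regions = regional_summary(sites)
        assert cells["n_individuals"].iloc[0] == 2

    def test_unknown_location_unassigned(self):
        from skiptrack.network import StopoverSite
        s = StopoverSite(0, GeoPoint(-150.0, -40.0), [])
        assign_regions([s])
        assert s.region == "UNASSIGNED"
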