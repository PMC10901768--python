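import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skiptrack.geo import (EARTH_RADIUS_KM, GeoPoint, ProjectionSpec,
                           gc_distance_km, gc_interpolate, great_circle_km,
                           grid_cell, grid_cells, point_to_segment_km,
                           project_equal_area, segments_min_distance_km)


def haversine_oracle(lon1, lat1, lon2, lat2):
    """Independent scalar haversine, written from the textbook formula."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    a = (math.sin((p2 - p1) / 2) ** 2
         + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * math.atan2(math.sqrt(a), math.sqrt(1 - a))


class TestGreatCircle:
    def test_identity_is_zero(self):
        p = GeoPoint(12.5, -33.0)
        assert great_circle_km(p, p) == 0.0

    def test_half_circumference(self):
        d = great_circle_km(GeoPoint(0, 0), GeoPoint(180, 0))
        assert d == pytest.approx(math.pi * EARTH_RADIUS_KM, rel=1e-12)

    def test_matches_independent_haversine(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            lon1, lon2 = rng.uniform(-180, 180, 2)
            lat1, lat2 = rng.uniform(-90, 90, 2)
            got = float(gc_distance_km(lon1, lat1, lon2, lat2))
            want = haversine_oracle(lon1, lat1, lon2, lat2)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            gc_distance_km(np.nan, 0, 0, 0)

    @given(st.tuples(*[st.floats(-180, 180) for _ in range(3)]),
           st.tuples(*[st.floats(-85, 85) for _ in range(3)]))
    @settings(max_examples=200, deadline=None)
    def test_triangle_inequality(self, lons, lats):
        a, b, c = (GeoPoint(lo, la) for lo, la in zip(lons, lats))
        assert great_circle_km(a, c) <= (great_circle_km(a, b)
                                         + great_circle_km(b, c) + 1e-6)


class TestProjection:
    def test_center_maps_to_origin(self):
        spec = ProjectionSpec(8.0, 54.0)
        xy = project_equal_area([GeoPoint(8.0, 54.0)], spec)
        assert np.allclose(xy, 0.0, atol=1e-9)

    def test_point_north_of_center(self):
        spec = ProjectionSpec(8.0, 54.0)
        north = GeoPoint(8.0, 54.0 + 1.0 / 111.195)  # ~1 km due north
        xy = project_equal_area([north], spec)
        assert xy[0, 1] == pytest.approx(1.0, rel=5e-3)
        assert abs(xy[0, 0]) < 1e-6

    def test_local_distances_preserved(self):
        spec = ProjectionSpec(8.0, 54.0)
        rng = np.random.default_rng(3)
        center = GeoPoint(8.0, 54.0)
        for _ in range(50):
            p = GeoPoint(8.0 + rng.uniform(-3, 3), 54.0 + rng.uniform(-2, 2))
            xy = project_equal_area([center, p], spec)
            planar = float(np.hypot(*(xy[1] - xy[0])))
            true = great_circle_km(center, p)
            if true > 1.0:
                assert planar == pytest.approx(true, rel=5e-3)

    def test_small_quad_area_preserved(self):
        # spherical-excess oracle for a small lon/lat quadrilateral
        spec = ProjectionSpec(8.0, 54.0)
        lon0, lon1, lat0, lat1 = 9.0, 10.0, 55.0, 56.0
        sphere_area = (EARTH_RADIUS_KM ** 2
                       * abs(math.radians(lon1 - lon0))
                       * abs(math.sin(math.radians(lat1)) - math.sin(math.radians(lat0))))
        corners = [GeoPoint(lon0, lat0), GeoPoint(lon1, lat0),
                   GeoPoint(lon1, lat1), GeoPoint(lon0, lat1)]
        xy = project_equal_area(corners, spec)
        x, y = xy[:, 0], xy[:, 1]
        planar_area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert planar_area == pytest.approx(sphere_area, rel=1e-3)

    def test_antipode_rejected(self):
        with pytest.raises(ValueError):
            project_equal_area([GeoPoint(-172.0, -54.0)], ProjectionSpec(8.0, 54.0))


class TestGrid:
    @pytest.mark.parametrize("xy,cell,expected", [
        ((0.0, 0.0), 300.0, (0, 0)),
        ((299.999, -0.001), 300.0, (0, -1)),
        ((450.0, 450.0), 300.0, (1, 1)),
    ])
    def test_half_open_convention(self, xy, cell, expected):
        assert grid_cell(xy, cell) == expected

    def test_non_positive_cell_rejected(self):
        with pytest.raises(ValueError):
            grid_cell((0, 0), 0.0)

    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, x, y):
        i, j = grid_cell((x, y), 300.0)
        assert i * 300.0 <= x < (i + 1) * 300.0
        assert j * 300.0 <= y < (j + 1) * 300.0


class TestPathGeometry:
    def test_interpolated_points_additive(self):
        a, b = GeoPoint(-15.8, 11.0), GeoPoint(70.0, 70.5)
        pts = gc_interpolate(a, b, np.linspace(0, 1, 50))
        d = gc_distance_km(pts[:-1, 0], pts[:-1, 1], pts[1:, 0], pts[1:, 1]).sum()
        assert d == pytest.approx(great_circle_km(a, b), rel=1e-9)

    def test_segment_distance_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            a = GeoPoint(rng.uniform(-10, 10), rng.uniform(30, 60))
            b = GeoPoint(rng.uniform(-10, 10), rng.uniform(30, 60))
            p = GeoPoint(rng.uniform(-12, 12), rng.uniform(28, 62))
            # dense sampling of the segment as the oracle
            dense = gc_interpolate(a, b, np.linspace(0, 1, 2000))
            brute = gc_distance_km(dense[:, 0], dense[:, 1], p.lon, p.lat).min()
            got = point_to_segment_km(a, b, p)
            assert got == pytest.approx(float(brute), rel=1e-3, abs=0.05)

    def test_vectorised_polyline_matches_scalar(self):
        rng = np.random.default_rng(5)
        lon = np.cumsum(rng.uniform(0, 2, 20)) - 5
        lat = np.cumsum(rng.uniform(0, 1, 20)) + 30
        p = GeoPoint(3.0, 40.0)
        scalar = min(point_to_segment_km(GeoPoint(lon[i], lat[i]),
                                         GeoPoint(lon[i + 1], lat[i + 1]), p)
                     for i in range(len(lon) - 1))
        assert segments_min_distance_km(lon, lat, p) == pytest.approx(scalar, rel=1e-9)


def test_geopoint_validation():
    with pytest.raises(ValueError):
        GeoPoint(0.0, 95.0)
    assert GeoPoint(190.0, 0.0).lon == pytest.approx(-170.0)
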