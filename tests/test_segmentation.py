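import numpy as np
import pandas as pd
import pytest

from skiptrack.filters import apply_quality_filters
from skiptrack.geo import GeoPoint
from skiptrack.io import Deployment
from skiptrack.segmentation import (BREEDING, RESIDENCY_LABELS, SPRING,
                                    STATIONARY, STOPOVER, SUMMERING,
                                    TRAVELLING, WINTERING, SegmentationParams,
                                    classify_phases, detect_stationary_runs,
                                    segment_track, split_migration_events)
from skiptrack.simulate import (DeviceModel, ItineraryStop, JourneySpec,
                                ORIGIN_ANCHORS, sample_device, simulate_journey)


def run_zero_noise(spec, deployment=None):
    path, truth = simulate_journey(spec)
    track, truth = sample_device(path, DeviceModel("GPS_UHF").zero_noise(),
                                 seed=0, deployment=deployment)
    clean, _ = apply_quality_filters(track)
    return clean, truth


class TestStationaryRuns:
    def test_jittered_cluster_is_one_run(self, make_track):
        rng = np.random.default_rng(4)
        lons = 10.0 + rng.uniform(-0.04, 0.04, 20)   # <=5 km jitter
        lats = 45.0 + rng.uniform(-0.04, 0.04, 20)
        tr = make_track(range(20), lons, lats)
        assert detect_stationary_runs(tr, 30.0) == [(0, 19)]

    def test_two_clusters_with_transit(self, make_track):
        lons = [0.0] * 8 + [1.5, 3.0, 4.5, 6.0] + [7.7] * 8
        lats = [45.0] * 8 + [45.0] * 4 + [45.0] * 8
        tr = make_track(range(20), lons, lats)
        runs = detect_stationary_runs(tr, 30.0)
        assert len(runs) == 2
        assert runs[0][0] == 0 and runs[1][1] == 19

    def test_pure_transit_has_no_runs(self, make_track):
        tr = make_track(range(10), np.arange(10) * 0.6, np.full(10, 45.0))
        assert detect_stationary_runs(tr, 30.0) == []


class TestClassifyPhases:
    def test_sub_50km_excursion_stays_wintering(self, make_track):
        # 40 km out and back inside the wintering area: no travelling phase
        hours = np.arange(0, 120)
        lons = np.zeros(120)
        lons[60:66] = 0.45   # ~40 km excursion at 45N for 6 h
        tr = make_track(hours, lons, np.full(120, 45.0))
        phases = classify_phases(tr)
        assert [p.label for p in phases] == [WINTERING]

    def test_short_stop_is_stationary_not_stopover(self):
        itin = (
            ItineraryStop(ORIGIN_ANCHORS["FR"], 10.0, WINTERING),
            ItineraryStop(GeoPoint(2.0, 50.0), 0.75, STATIONARY),   # 18 h stop
            ItineraryStop(GeoPoint(8.5, 54.3), 3.0, STOPOVER),
            ItineraryStop(GeoPoint(40.0, 66.0), 30.0, BREEDING),
        )
        spec = JourneySpec("b", "FR", itin, pd.Timestamp("2022-04-25", tz="UTC"))
        clean, truth = run_zero_noise(spec)
        phases, _ = segment_track(clean)
        labels = [p.label for p in phases if p.label != TRAVELLING]
        assert labels == [WINTERING, STATIONARY, STOPOVER, BREEDING]

    def test_zero_noise_journey_matches_ground_truth(self):
        itin = (
            ItineraryStop(ORIGIN_ANCHORS["PT"], 15.0, WINTERING),
            ItineraryStop(GeoPoint(-1.5, 46.0), 4.0, STOPOVER),
            ItineraryStop(GeoPoint(8.5, 54.3), 6.0, STOPOVER),
            ItineraryStop(GeoPoint(40.0, 66.5), 2.0, STOPOVER),
            ItineraryStop(GeoPoint(70.0, 70.5), 30.0, BREEDING),
        )
        spec = JourneySpec("b", "PT", itin, pd.Timestamp("2022-04-20", tz="UTC"))
        clean, truth = run_zero_noise(spec)
        phases, events = segment_track(clean)
        stops = [p for p in phases if p.label == STOPOVER]
        assert len(stops) == 3
        # phase boundaries within one sampling interval (1 h) of truth
        for p, s in zip(stops, truth.journeys[0].stops):
            assert abs((p.t_start - s.t_arrive).total_seconds()) <= 3600
            assert abs((p.t_end - s.t_depart).total_seconds()) <= 3600

    def test_no_residency_anchor_is_all_travelling(self, make_track):
        tr = make_track(np.arange(30), np.arange(30) * 0.7, np.full(30, 45.0))
        phases = classify_phases(tr)
        assert [p.label for p in phases] == [TRAVELLING]

    def test_phases_cover_track_exactly(self, zero_noise_cohort):
        for track, _ in zero_noise_cohort[:5]:
            clean, _ = apply_quality_filters(track)
            phases = classify_phases(clean)
            spans = [(p.i0, p.i1) for p in phases]
            assert spans[0][0] == 0 and spans[-1][1] == len(clean) - 1
            for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
                assert b0 == a1 + 1

    def test_stop_duration_invariants(self, zero_noise_cohort):
        for track, _ in zero_noise_cohort[:5]:
            clean, _ = apply_quality_filters(track)
            phases = classify_phases(clean)
            for p in phases:
                if p.label == STOPOVER:
                    assert p.duration_h > 24.0
                if p.label == STATIONARY:
                    assert p.duration_h <= 24.0


class TestMigrationEvents:
    def test_annual_track_gives_two_complete_events(self):
        from skiptrack.simulate import make_journey_spec
        spec = make_journey_spec("b", "PT", seed=5, annual=True)
        clean, truth = run_zero_noise(spec)
        _, events = segment_track(clean)
        complete = [e for e in events if e.complete]
        assert len(complete) == 2
        assert {e.season for e in complete} == {"SPRING", "AUTUMN"}

    def test_track_lost_en_route_is_incomplete(self):
        from skiptrack.simulate import make_journey_spec
        spec = make_journey_spec("b", "GB", seed=2)
        path, truth = simulate_journey(spec)
        track, _ = sample_device(path, DeviceModel("GPS_UHF").zero_noise(), seed=0)
        # truncate mid-way through the third stopover
        cut = truth.journeys[0].stops[2].t_arrive + pd.Timedelta(hours=30)
        short = track.with_fixes(track.fixes[track.fixes["timestamp"] <= cut])
        clean, _ = apply_quality_filters(short)
        _, events = segment_track(clean)
        assert events and events[-1].complete is False

    def test_summering_destination_for_second_cy(self):
        itin = (
            ItineraryStop(ORIGIN_ANCHORS["GB"], 15.0, WINTERING),
            ItineraryStop(GeoPoint(-9.0, 38.7), 3.0, STOPOVER),
            ItineraryStop(GeoPoint(8.5, 54.3), 45.0, SUMMERING),
        )
        spec = JourneySpec("b", "GB", itin, pd.Timestamp("2022-05-01", tz="UTC"))
        clean, _ = run_zero_noise(
            spec, deployment=Deployment(tagging_site="GB", age_class="second_cy"))
        phases, events = segment_track(clean)
        assert phases[-1].label == SUMMERING
        assert events[-1].complete and events[-1].season == SPRING

    def test_every_fix_in_exactly_one_phase(self, zero_noise_cohort):
        track, _ = zero_noise_cohort[0]
        clean, _ = apply_quality_filters(track)
        phases = classify_phases(clean)
        covered = np.concatenate([np.arange(p.i0, p.i1 + 1) for p in phases])
        assert len(covered) == len(clean)
        assert len(np.unique(covered)) == len(clean)
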