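"""Flight-log synchronisation and footprint-projection tests."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

import aerosurvey as a
from aerosurvey.georef import (OBLIQUE_UNCERTAINTY_M, FlightLog, ImageEvent,
                               TrackState, coverage_union,
                               footprints_to_geojson, world_file_lines)

T0 = dt.datetime(2012, 8, 15, 9, 0, 0)


def make_log(n=11, hz=10.0, lat0=-28.2, lon0=31.95, alt=150.0, course=0.0,
             speed=30.0):
    """Straight northbound track at constant speed."""
    ms = speed / 3.6
    proj = a.LocalTransverseMercator(lat0, lon0)
    t = np.arange(n) / hz
    lon, lat = proj.to_lonlat(np.zeros(n), ms * t)
    return FlightLog(records=pd.DataFrame({
        "time": pd.Timestamp(T0) + pd.to_timedelta(t, unit="s"),
        "lat": lat, "lon": lon,
        "alt_agl_m": np.full(n, alt),
        "course_deg": np.full(n, course),
        "speed_kmh": np.full(n, speed),
    }))


class TestSync:
    def test_event_on_exact_fix_returns_that_fix(self, still_cam):
        log = make_log()
        ev = ImageEvent(timestamp=T0 + dt.timedelta(seconds=0.5),
                        camera=still_cam, image_id="i5")
        state = a.sync_event_to_track(log, ev)
        row = log.records.iloc[5]
        assert state.lat == pytest.approx(row.lat)
        assert state.lon == pytest.approx(row.lon)
        assert state.alt_agl_m == pytest.approx(row.alt_agl_m)

    def test_midpoint_between_fixes_interpolates_linearly(self, still_cam):
        log = make_log()
        ev = ImageEvent(timestamp=T0 + dt.timedelta(seconds=0.25),
                        camera=still_cam, image_id="mid")
        state = a.sync_event_to_track(log, ev)
        r2, r3 = log.records.iloc[2], log.records.iloc[3]
        assert state.lat == pytest.approx((r2.lat + r3.lat) / 2)
        assert state.alt_agl_m == pytest.approx((r2.alt_agl_m + r3.alt_agl_m) / 2)

    def test_event_before_log_span_errors(self, still_cam):
        log = make_log()
        ev = ImageEvent(timestamp=T0 - dt.timedelta(seconds=5),
                        camera=still_cam, image_id="early")
        with pytest.raises(ValueError, match="outside log span"):
            a.sync_event_to_track(log, ev)

    def test_clock_offset_shifts_event_into_span(self, still_cam):
        log = make_log()
        ev = ImageEvent(timestamp=T0 - dt.timedelta(seconds=0.5),
                        camera=still_cam, image_id="skewed")
        state = a.sync_event_to_track(log, ev, clock_offset_s=0.5)
        assert state.lat == pytest.approx(log.records.iloc[0].lat)

    def test_course_interpolates_circularly_across_north(self, still_cam):
        # 350 deg and 10 deg straddle north: interpolated course is ~0, not 180
        log = make_log()
        df = log.records.copy()
        df["course_deg"] = np.where(np.arange(len(df)) < 5, 350.0, 10.0)
        log = FlightLog(records=df)
        ev = ImageEvent(timestamp=T0 + dt.timedelta(seconds=0.45),
                        camera=still_cam, image_id="turn")
        state = a.sync_event_to_track(log, ev)
        assert min(state.course_deg, 360 - state.course_deg) < 20.0

    def test_non_increasing_timestamps_rejected(self):
        df = make_log().records.copy()
        df.loc[3, "time"] = df.loc[2, "time"]
        with pytest.raises(ValueError, match="strictly increasing"):
            FlightLog(records=df)


class TestNadirProjection:
    def test_footprint_dims_and_orientation(self, still_cam):
        state = TrackState(time=pd.Timestamp(T0), lat=-28.2, lon=31.95,
                           alt_agl_m=100.0, course_deg=0.0, speed_kmh=30.0)
        fpn = a.project_nadir_footprint(state, still_cam, "img")
        proj = a.LocalTransverseMercator(state.lat, state.lon)
        poly = proj.project_geometry(fpn.polygon)
        minx, miny, maxx, maxy = poly.bounds
        assert maxy - miny == pytest.approx(109.8, abs=0.1)   # along track (N)
        assert maxx - minx == pytest.approx(158.2, abs=0.1)   # across track
        assert maxx - minx > maxy - miny  # long axis across-track

    @pytest.mark.parametrize("h", [1.0, 50.0, 260.0])
    @pytest.mark.parametrize("course", [0.0, 37.0, 200.0])
    def test_sub_aircraft_point_inside_footprint(self, still_cam, h, course):
        state = TrackState(time=pd.Timestamp(T0), lat=-28.2, lon=31.95,
                           alt_agl_m=h, course_deg=course, speed_kmh=30.0)
        fpn = a.project_nadir_footprint(state, still_cam, "img")
        assert fpn.polygon.contains(Point(state.lon, state.lat))

    def test_zero_altitude_flagged_degenerate(self, still_cam):
        state = TrackState(time=pd.Timestamp(T0), lat=-28.2, lon=31.95,
                           alt_agl_m=0.0, course_deg=0.0, speed_kmh=30.0)
        fpn = a.project_nadir_footprint(state, still_cam, "img")
        assert fpn.degenerate and fpn.polygon is None

    def test_consecutive_exposures_overlap_matches_closed_form(self, still_cam):
        # two exposures 1/P apart at high overlap: polygon intersection area
        # over single-footprint area must match the analytic overlap
        fp = a.FlightParams(260.0, 15.0)
        log = make_log(n=31, alt=260.0, speed=15.0)
        ev = [ImageEvent(T0 + dt.timedelta(seconds=s / still_cam.fps),
                         still_cam, f"i{s}") for s in range(2)]
        f0, f1 = a.georeference_events(log, ev)
        proj = a.LocalTransverseMercator(-28.2, 31.95)
        p0 = proj.project_geometry(f0.polygon)
        p1 = proj.project_geometry(f1.polygon)
        measured = 100.0 * p0.intersection(p1).area / p0.area
        assert measured == pytest.approx(a.along_track_overlap(still_cam, fp),
                                         abs=0.1)


class TestObliqueProjection:
    def test_ground_point_ahead_by_h_over_tan_depression(self, hd_cam):
        state = TrackState(time=pd.Timestamp(T0), lat=-28.2, lon=31.95,
                           alt_agl_m=100.0, course_deg=0.0, speed_kmh=30.0)
        gp = a.project_oblique_ground_point(state, hd_cam, "frame")
        proj = a.LocalTransverseMercator(state.lat, state.lon)
        x, y = proj.to_xy(gp.center_lon, gp.center_lat)
        assert float(x) == pytest.approx(0.0, abs=0.01)
        assert float(y) == pytest.approx(100.0 / math.tan(math.radians(30.0)),
                                         abs=0.01)  # ~173.2 m
        assert gp.positional_uncertainty_m == OBLIQUE_UNCERTAINTY_M == 50.0

    def test_nadir_limit_collapses_to_sub_aircraft_point(self, still_cam):
        state = TrackState(time=pd.Timestamp(T0), lat=-28.2, lon=31.95,
                           alt_agl_m=100.0, course_deg=45.0, speed_kmh=30.0)
        gp = a.project_oblique_ground_point(state, still_cam, "frame")
        assert gp.center_lat == pytest.approx(state.lat, abs=1e-9)
        assert gp.center_lon == pytest.approx(state.lon, abs=1e-9)

    def test_horizon_mount_has_no_ground_intersection(self):
        from aerosurvey.cameras import CameraModel
        with pytest.raises(ValueError, match="mount_depression"):
            CameraModel(name="horizon", fov_diag_deg=90.0, px_h=100, px_v=100,
                        mount_depression_deg=0.0)


class TestCoverageUnion:
    def _footprints(self, still_cam, n, speed):
        log = make_log(n=1 + int(50 * 10), alt=150.0, speed=speed)
        events = [ImageEvent(T0 + dt.timedelta(seconds=s / still_cam.fps),
                             still_cam, f"i{s}") for s in range(n)]
        return a.georeference_events(log, events)

    def test_single_footprint_union_is_itself(self, still_cam):
        fps = self._footprints(still_cam, 1, 30.0)
        proj = a.LocalTransverseMercator(-28.2, 31.95)
        area = proj.project_geometry(fps[0].polygon).area / 1e4
        out = coverage_union(fps)
        assert out["covered_area_ha"] == pytest.approx(area, rel=1e-6)

    def test_union_bounded_by_single_and_total_area(self, still_cam):
        fps = self._footprints(still_cam, 10, 40.0)
        proj = a.LocalTransverseMercator(-28.2, 31.95)
        single = proj.project_geometry(fps[0].polygon).area / 1e4
        out = coverage_union(fps)
        assert single - 1e-6 <= out["covered_area_ha"] <= 10 * single + 1e-6

    def test_overlapping_strip_arithmetic(self, still_cam):
        # at 50% overlap, n exposures cover footprint_len * (1 + (n-1)/2)
        h = 150.0
        length = still_cam.k_along * h
        speed_ms = 0.5 * length * still_cam.fps
        fps = self._footprints(still_cam, 5, speed_ms * 3.6)
        width = still_cam.k_across * h
        expect_ha = length * (1 + (5 - 1) / 2) * width / 1e4
        out = coverage_union(fps)
        assert out["covered_area_ha"] == pytest.approx(expect_ha, rel=0.01)


class TestIO:
    def test_csv_roundtrip(self, tmp_path, still_cam):
        log = make_log()
        p = tmp_path / "log.csv"
        log.records.to_csv(p, index=False)
        back = a.read_flight_log_csv(p)
        assert np.allclose(back.records["lat"], log.records["lat"])
        assert (back.records["time"] == log.records["time"]).all()

    def test_gpx_requires_agl_assertion(self, tmp_path):
        gpx = tmp_path / "t.gpx"
        pts = "".join(
            f'<trkpt lat="{-28.2 + i * 1e-5}" lon="31.95"><ele>150</ele>'
            f'<time>2012-08-15T09:00:{i:02d}Z</time></trkpt>'
            for i in range(5))
        gpx.write_text('<gpx xmlns="http://www.topografix.com/GPX/1/1">'
                       f'<trk><trkseg>{pts}</trkseg></trk></gpx>')
        with pytest.raises(ValueError, match="assume_agl"):
            a.read_flight_log_gpx(gpx)
        log = a.read_flight_log_gpx(gpx, assume_agl=True)
        assert len(log.records) == 5
        assert log.records["course_deg"].iloc[1] == pytest.approx(0.0, abs=1.0)

    def test_geojson_features_carry_properties(self, still_cam):
        log = make_log()
        ev = [ImageEvent(T0 + dt.timedelta(seconds=0.2), still_cam, "img1")]
        gj = footprints_to_geojson(a.georeference_events(log, ev))
        assert gj["type"] == "FeatureCollection"
        props = gj["features"][0]["properties"]
        assert props["image_id"] == "img1"
        assert props["h_agl"] == pytest.approx(150.0)
        assert props["gsd_cm"] == pytest.approx(150 * 11.8 / 260, rel=1e-6)

    def test_world_file_has_six_lines_matching_bbox(self, still_cam):
        log = make_log()
        ev = [ImageEvent(T0 + dt.timedelta(seconds=0.2), still_cam, "img1")]
        fpn = a.georeference_events(log, ev)[0]
        lines = world_file_lines(fpn, still_cam)
        assert len(lines) == 6
        A, D, B, E, C, F = (float(v) for v in lines)
        minx, miny, maxx, maxy = fpn.polygon.bounds
        assert A > 0 > E
        assert C == pytest.approx(minx + A / 2)
        assert F == pytest.approx(maxy + E / 2)
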