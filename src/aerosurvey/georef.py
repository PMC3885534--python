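"""Geo-referencing camera events against a GPS + barometric flight log.

The aircraft records a ~10 Hz track (position, barometric altitude AGL,
course, speed) while a camera fires on its own clock.  Matching an exposure
timestamp against the track — with an optional clock-offset correction —
yields the aircraft state at exposure time, from which the ground footprint
of a nadir camera (or the ground point on the optical axis of an oblique
video camera) is projected and emitted as GeoJSON, with optional ESRI world
files.

Oblique video placements carry a documented 50 m positional uncertainty:
frame timing against the track bounds the target position to roughly that
radius without a full photogrammetric solution.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping
from shapely import unary_union

from .cameras import CameraModel, footprint_dims
from .projection import LocalTransverseMercator

#: documented placement precision for oblique video frames, m
OBLIQUE_UNCERTAINTY_M = 50.0

LOG_COLUMNS = ["time", "lat", "lon", "alt_agl_m", "course_deg", "speed_kmh"]


@dataclass(frozen=True)
class FlightLog:
    """An ordered 10 Hz-class aircraft track.

    ``records`` is a DataFrame with columns ``time`` (datetime64), ``lat``,
    ``lon`` (degrees WGS84), ``alt_agl_m`` (barometric altitude AGL),
    ``course_deg`` (from true north) and ``speed_kmh``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in LOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"flight log missing columns: {missing}")
        if len(df) < 2:
            raise ValueError("flight log needs at least two fixes")
        t = df["time"].to_numpy()
        if not (np.diff(t.astype("datetime64[ns]").astype(np.int64)) > 0).all():
            raise ValueError("flight-log timestamps must be strictly increasing")
        if (df["alt_agl_m"] < 0).any():
            raise ValueError("barometric altitude AGL cannot be negative")

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.records["time"].iloc[0], self.records["time"].iloc[-1]


@dataclass(frozen=True)
class ImageEvent:
    timestamp: _dt.datetime
    camera: CameraModel
    image_id: str


@dataclass(frozen=True)
class TrackState:
    """Interpolated aircraft state at an instant."""

    time: pd.Timestamp
    lat: float
    lon: float
    alt_agl_m: float
    course_deg: float
    speed_kmh: float


@dataclass(frozen=True)
class GeoFootprint:
    """Ground footprint (or ground point) of one exposure."""

    image_id: str
    center_lon: float
    center_lat: float
    polygon: Optional[Polygon]  # lon/lat quadrilateral; None for point placements
    gsd_cm: Optional[float]
    h_agl_m: float
    positional_uncertainty_m: float = 0.0
    degenerate: bool = False


# ---------------------------------------------------------------------------
# log readers

def read_flight_log_csv(path) -> FlightLog:
    """Read a CSV flight log (header: time,lat,lon,alt_agl_m,course_deg,speed_kmh)."""
    df = pd.read_csv(path, parse_dates=["time"])
    return FlightLog(records=df[LOG_COLUMNS])


def read_flight_log_gpx(path, assume_agl: bool = False) -> FlightLog:
    """Read a GPX track as a flight log.

    GPX ``<ele>`` is normally ellipsoidal/MSL elevation; it is accepted as
    barometric AGL only when the caller asserts ``assume_agl=True``.  Course
    and speed are reconstructed from consecutive fixes.
    """
    if not assume_agl:
        raise ValueError("GPX elevation is not AGL; pass assume_agl=True to "
                         "assert barometric-AGL semantics")
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    root = ElementTree.parse(path).getroot()
    rows = []
    for pt in root.iterfind(".//gpx:trkpt", ns):
        ele = pt.find("gpx:ele", ns)
        t = pt.find("gpx:time", ns)
        if ele is None or t is None:
            continue
        rows.append((pd.Timestamp(t.text).tz_localize(None)
                     if pd.Timestamp(t.text).tzinfo else pd.Timestamp(t.text),
                     float(pt.get("lat")), float(pt.get("lon")), float(ele.text)))
    if len(rows) < 2:
        raise ValueError("GPX track has fewer than two usable points")
    df = pd.DataFrame(rows, columns=["time", "lat", "lon", "alt_agl_m"])
    proj = LocalTransverseMercator.centered_on_points(df["lon"], df["lat"])
    x, y = proj.to_xy(df["lon"].to_numpy(), df["lat"].to_numpy())
    dt = df["time"].diff().dt.total_seconds().to_numpy()
    dx, dy = np.diff(x), np.diff(y)
    course = np.degrees(np.arctan2(dx, dy)) % 360.0
    speed = np.hypot(dx, dy) / dt[1:] * 3.6
    df["course_deg"] = np.concatenate([[course[0]], course])
    df["speed_kmh"] = np.concatenate([[speed[0]], speed])
    return FlightLog(records=df)


# ---------------------------------------------------------------------------
# synchronisation

def sync_event_to_track(log: FlightLog, event: ImageEvent,
                        clock_offset_s: float = 0.0) -> TrackState:
    """Interpolate the aircraft state at an exposure time.

    ``clock_offset_s`` is added to the event timestamp before matching
    (camera clock ahead of GPS clock -> negative offset).  Position and
    altitude interpolate linearly between the bracketing fixes; course
    interpolates circularly.  Events outside the log span are an error —
    extrapolation is never attempted.
    """
    t = pd.Timestamp(event.timestamp) + pd.to_timedelta(clock_offset_s, unit="s")
    t0, t1 = log.span
    if not t0 <= t <= t1:
        raise ValueError(f"event {event.image_id!r} at {t} outside log span "
                         f"[{t0}, {t1}] (after clock offset {clock_offset_s:+g} s)")
    df = log.records
    tt = df["time"].astype("datetime64[ns]").astype(np.int64).to_numpy()
    tq = pd.Timestamp(t).value
    lat = float(np.interp(tq, tt, df["lat"].to_numpy()))
    lon = float(np.interp(tq, tt, df["lon"].to_numpy()))
    alt = float(np.interp(tq, tt, df["alt_agl_m"].to_numpy()))
    speed = float(np.interp(tq, tt, df["speed_kmh"].to_numpy()))
    crs = np.radians(df["course_deg"].to_numpy())
    course = math.degrees(math.atan2(
        np.interp(tq, tt, np.sin(crs)), np.interp(tq, tt, np.cos(crs)))) % 360.0
    return TrackState(time=t, lat=lat, lon=lon, alt_agl_m=alt,
                      course_deg=course, speed_kmh=speed)


# ---------------------------------------------------------------------------
# projection to the ground

def project_nadir_footprint(state: TrackState, camera: CameraModel,
                            image_id: str = "") -> GeoFootprint:
    """Ground rectangle imaged by a nadir camera at ``state``.

    The footprint is centred on the sub-aircraft point and rotated to the
    course over ground (attitude is ignored; wind-induced distortion is
    accepted).  At h = 0 the footprint degenerates to a point and is flagged.
    """
    if not camera.is_nadir:
        raise ValueError("camera is not nadir-mounted; use "
                         "project_oblique_ground_point")
    dims = footprint_dims(camera, state.alt_agl_m)
    proj = LocalTransverseMercator(lat0=state.lat, lon0=state.lon)
    if state.alt_agl_m == 0:
        return GeoFootprint(image_id=image_id, center_lon=state.lon,
                            center_lat=state.lat, polygon=None,
                            gsd_cm=dims.gsd_cm, h_agl_m=0.0, degenerate=True)
    half_l, half_w = dims.along_track_m / 2.0, dims.across_track_m / 2.0
    theta = math.radians(state.course_deg)
    along = np.array([math.sin(theta), math.cos(theta)])   # unit along course
    across = np.array([math.cos(theta), -math.sin(theta)])
    corners_xy = [tuple(sa * half_l * along + sb * half_w * across)
                  for sa, sb in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
    poly = proj.unproject_geometry(Polygon(corners_xy))
    return GeoFootprint(image_id=image_id, center_lon=state.lon,
                        center_lat=state.lat, polygon=poly, gsd_cm=dims.gsd_cm,
                        h_agl_m=state.alt_agl_m)


def project_oblique_ground_point(state: TrackState, camera: CameraModel,
                                 image_id: str = "") -> GeoFootprint:
    """Ground point on the optical axis of a forward-looking oblique camera.

    The axis meets the ground ``h / tan(depression)`` metres ahead of the
    sub-aircraft point along the course; at 90° depression this collapses to
    the nadir point.  The placement carries the documented 50 m uncertainty.
    """
    dep = camera.mount_depression_deg
    if dep <= 0:
        raise ValueError("no ground intersection: mount depression must be > 0°")
    ahead = state.alt_agl_m / math.tan(math.radians(dep))
    proj = LocalTransverseMercator(lat0=state.lat, lon0=state.lon)
    theta = math.radians(state.course_deg)
    lon, lat = proj.to_lonlat(ahead * math.sin(theta), ahead * math.cos(theta))
    return GeoFootprint(image_id=image_id, center_lon=float(lon),
                        center_lat=float(lat), polygon=None,
                        gsd_cm=footprint_dims(camera, state.alt_agl_m).gsd_cm,
                        h_agl_m=state.alt_agl_m,
                        positional_uncertainty_m=OBLIQUE_UNCERTAINTY_M)


def georeference_events(log: FlightLog, events: Iterable[ImageEvent],
                        clock_offset_s: float = 0.0) -> list[GeoFootprint]:
    """Sync and project a whole event stream against a flight log."""
    out = []
    for ev in events:
        state = sync_event_to_track(log, ev, clock_offset_s)
        if ev.camera.is_nadir:
            out.append(project_nadir_footprint(state, ev.camera, ev.image_id))
        else:
            out.append(project_oblique_ground_point(state, ev.camera, ev.image_id))
    return out


# ---------------------------------------------------------------------------
# coverage analysis

def coverage_union(footprints: Sequence[GeoFootprint],
                   survey_polygon: Optional[Polygon] = None) -> dict:
    """Union the footprints and report covered area and residual gaps.

    Returns ``covered_area_ha`` (union area, intersected with the survey
    polygon when given), ``gap_polygons`` (uncovered parts of the survey
    polygon, lon/lat) and ``gap_area_ha``.
    """
    polys = [f.polygon for f in footprints if f.polygon is not None]
    if not polys:
        raise ValueError("no areal footprints to union")
    ref = unary_union(polys)
    proj = LocalTransverseMercator.centered_on(ref)
    union_xy = unary_union([proj.project_geometry(p) for p in polys])
    if survey_polygon is not None:
        poly_xy = proj.project_geometry(survey_polygon)
        covered = union_xy.intersection(poly_xy)
        gaps = poly_xy.difference(union_xy)
    else:
        covered, gaps = union_xy, None
    out = {"covered_area_ha": covered.area / 1e4,
           "gap_area_ha": (gaps.area / 1e4) if gaps is not None else 0.0,
           "gap_polygons": []}
    if gaps is not None and not gaps.is_empty:
        parts = gaps.geoms if hasattr(gaps, "geoms") else [gaps]
        out["gap_polygons"] = [proj.unproject_geometry(g) for g in parts
                               if g.geom_type == "Polygon"]
    return out


# ---------------------------------------------------------------------------
# output writers

def footprints_to_geojson(footprints: Sequence[GeoFootprint]) -> dict:
    """GeoJSON FeatureCollection of footprint polygons / placement points."""
    features = []
    for f in footprints:
        geom = (mapping(f.polygon) if f.polygon is not None
                else {"type": "Point", "coordinates": [f.center_lon, f.center_lat]})
        features.append({
            "type": "Feature",
            "geometry": geom,
            "properties": {
                "image_id": f.image_id,
                "gsd_cm": f.gsd_cm,
                "h_agl": f.h_agl_m,
                "uncertainty_m": f.positional_uncertainty_m,
                "degenerate": f.degenerate,
            },
        })
    return {"type": "FeatureCollection", "features": features}


def write_footprints_geojson(footprints: Sequence[GeoFootprint], path) -> None:
    with open(path, "w") as fh:
        json.dump(footprints_to_geojson(footprints), fh, indent=1)


def world_file_lines(footprint: GeoFootprint, camera: CameraModel) -> list[str]:
    """Six-line ESRI world file for the footprint's north-up bounding box.

    The affine maps pixel centres onto the axis-aligned lon/lat bounding box
    of the (possibly rotated) footprint; the rotation itself lives in the
    GeoJSON sidecar.  Pixel counts default to 1000 x 1000 when the camera
    profile has none.
    """
    if footprint.polygon is None:
        raise ValueError("point placements have no world file")
    minx, miny, maxx, maxy = footprint.polygon.bounds
    px_h = camera.px_h or 1000
    px_v = camera.px_v or 1000
    a = (maxx - minx) / px_h
    e = -(maxy - miny) / px_v
    c = minx + a / 2.0
    f = maxy + e / 2.0
    return [f"{v:.12f}" for v in (a, 0.0, 0.0, e, c, f)]


def write_world_file(footprint: GeoFootprint, camera: CameraModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(world_file_lines(footprint, camera)) + "\n")
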