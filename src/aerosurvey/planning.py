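"""Lawnmower transect planning and mission feasibility checks.

Given a survey polygon and a camera flown at a chosen altitude, the planner
lays parallel transects spaced ``swath * (1 - sidelap/100)`` apart, clipped
to the polygon and ordered serpentine-fashion, then scores the mission
against the airframe's constraints (endurance, radio range, wind limit and
the recommended altitude band).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import (LineString, MultiLineString, MultiPolygon, Point,
                              Polygon, mapping, shape)
from shapely.geometry import box as shp_box
from shapely import affinity, unary_union

from .cameras import CameraModel, FlightParams, footprint_dims
from .projection import LocalTransverseMercator

#: recommended operating envelope for the reference small fixed-wing RPAS:
#: 10 km radio range, 50 min endurance, safe below ~15 km/h wind, and a
#: 100-180 m AGL band that balances image quality, safety and discretion.
DEFAULT_CONSTRAINTS_KW = dict(max_range_km=10.0, endurance_min=50.0,
                              wind_limit_kmh=15.0, altitude_band=(100.0, 180.0))


@dataclass(frozen=True)
class SurveyArea:
    """A named survey polygon in WGS84 lon/lat."""

    polygon: Polygon | MultiPolygon
    name: str = "survey-area"

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError("survey polygon must be a valid, non-empty polygon")
        if self.polygon.area <= 0:
            raise ValueError("survey polygon must enclose a positive area")

    @classmethod
    def from_geojson(cls, path: str, name: Optional[str] = None) -> "SurveyArea":
        import json
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            gj = gj["features"][0]
        props = gj.get("properties") or {}
        geom = gj["geometry"] if gj.get("type") == "Feature" else gj
        return cls(polygon=shape(geom), name=name or props.get("name", "survey-area"))


@dataclass(frozen=True)
class MissionConstraints:
    max_range_km: float
    endurance_min: float
    wind_limit_kmh: float
    altitude_band: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.max_range_km, self.endurance_min, self.wind_limit_kmh) <= 0:
            raise ValueError("constraints must be positive")
        lo, hi = self.altitude_band
        if not 0 < lo < hi:
            raise ValueError("altitude band must satisfy 0 < min < max")

    @classmethod
    def default(cls) -> "MissionConstraints":
        return cls(**DEFAULT_CONSTRAINTS_KW)


@dataclass(frozen=True)
class TransectPlan:
    """A serpentine transect plan over a survey polygon.

    ``waypoints`` are (lon, lat) pairs, transect endpoints in flying order.
    ``transects_xy`` keeps the metric-frame segments for geometry checks.
    ``total_path_length_km`` counts transect legs only; turns between legs
    are reported as ``n_turns`` and costed separately by the operator.
    """

    waypoints: tuple
    line_spacing_m: float
    swath_m: float
    sidelap_pct: float
    heading_deg: float
    h_agl_m: float
    total_path_length_km: float
    n_transects: int
    n_turns: int
    area_name: str = "survey-area"
    projection: Optional[LocalTransverseMercator] = None
    transects_xy: tuple = ()
    est_flight_time_min: Optional[float] = None
    n_sorties: Optional[int] = None
    out_of_range_waypoints: tuple = ()

    def waypoint_lines_wgs84(self) -> list[LineString]:
        return [self.projection.unproject_geometry(LineString(seg))
                for seg in self.transects_xy]


def plan_lawnmower(
    area: SurveyArea,
    camera: CameraModel,
    h: float,
    sidelap: float = 20.0,
    heading: Optional[float] = None,
    overshoot_m: Optional[float] = None,
) -> TransectPlan:
    """Lay serpentine transects over ``area`` for ``camera`` at ``h`` m AGL.

    Transects run along ``heading`` (degrees from true north; default: the
    long axis of the polygon's minimum rotated rectangle, which minimises
    turns) and are spaced ``swath * (1 - sidelap/100)`` apart.  The first and
    last lines sit at most half a spacing from the polygon edge, so every
    interior point lies within swath/2 of a transect whenever sidelap >= 0.
    Each transect is extended ``overshoot_m`` (default: half a swath) beyond
    the boundary at both ends — the usual lead-in/lead-out that keeps corner
    slivers imaged.
    """
    if not 0 <= sidelap < 100:
        raise ValueError("sidelap must be in [0, 100)")
    band_lo, band_hi = DEFAULT_CONSTRAINTS_KW["altitude_band"]
    if not band_lo <= h <= band_hi:
        warnings.warn(f"altitude {h} m AGL is outside the recommended "
                      f"{band_lo:.0f}-{band_hi:.0f} m band", stacklevel=2)
    swath = footprint_dims(camera, h).across_track_m
    spacing = swath * (1.0 - sidelap / 100.0)
    if spacing <= 0:
        raise ValueError("transect spacing is zero: altitude or swath too small")
    if overshoot_m is None:
        overshoot_m = swath / 2.0

    proj = LocalTransverseMercator.centered_on(area.polygon)
    poly_xy = proj.project_geometry(area.polygon)

    if heading is None:
        heading = _long_axis_heading(poly_xy)

    # rotate so transects run along +x, lay horizontal lines, rotate back
    rot = affinity.rotate(poly_xy, heading - 90.0, origin=(0, 0), use_radians=False)
    minx, miny, maxx, maxy = rot.bounds
    height = maxy - miny
    n_lines = max(1, math.ceil(height / spacing))
    margin = (height - (n_lines - 1) * spacing) / 2.0
    ys = miny + margin + spacing * np.arange(n_lines)

    segments: list[tuple] = []
    for i, y in enumerate(ys):
        # each transect images the half-spacing band either side of its row,
        # so clip it to the polygon's extent over that whole band (a line
        # clipped only at its own row misses wide spots near apexes)
        band = rot.intersection(shp_box(minx - 1.0, y - spacing / 2.0,
                                        maxx + 1.0, y + spacing / 2.0))
        spans = sorted((p.bounds[0], p.bounds[2]) for p in _as_polys(band))
        spans = [(x0 - overshoot_m, x1 + overshoot_m) for x0, x1 in spans]
        if i % 2 == 1:  # serpentine: reverse every other line
            spans = [(x1, x0) for x0, x1 in reversed(spans)]
        for xa, xb in spans:
            back = affinity.rotate(LineString([(xa, y), (xb, y)]),
                                   90.0 - heading, origin=(0, 0),
                                   use_radians=False)
            segments.append(tuple(back.coords))

    if not segments:
        raise ValueError("polygon produced no transects (degenerate geometry)")

    path_m = sum(LineString(seg).length for seg in segments)
    waypoints = []
    for seg in segments:
        for x, y in (seg[0], seg[-1]):
            lon, lat = proj.to_lonlat(x, y)
            waypoints.append((float(lon), float(lat)))

    return TransectPlan(
        waypoints=tuple(waypoints),
        line_spacing_m=spacing,
        swath_m=swath,
        sidelap_pct=sidelap,
        heading_deg=float(heading) % 360.0,
        h_agl_m=h,
        total_path_length_km=path_m / 1000.0,
        n_transects=len(segments),
        n_turns=len(segments) - 1,
        area_name=area.name,
        projection=proj,
        transects_xy=tuple(segments),
    )


def _long_axis_heading(poly_xy: Polygon) -> float:
    rect = poly_xy.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate (line-like) polygon
        return 90.0
    coords = list(rect.exterior.coords)
    best = max((LineString([coords[i], coords[i + 1]]) for i in range(4)),
               key=lambda ls: ls.length)
    (x0, y0), (x1, y1) = best.coords
    return math.degrees(math.atan2(x1 - x0, y1 - y0)) % 180.0


def _as_polys(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if hasattr(geom, "geoms"):  # Multi*/GeometryCollection: keep areal parts
        out = []
        for g in geom.geoms:
            out.extend(_as_polys(g))
        return out
    return []


def covered_fraction(plan: TransectPlan, area: SurveyArea) -> float:
    """Fraction of the polygon within swath/2 of some transect."""
    poly_xy = plan.projection.project_geometry(area.polygon)
    strips = unary_union([LineString(seg).buffer(plan.swath_m / 2.0)
                          for seg in plan.transects_xy])
    return strips.intersection(poly_xy).area / poly_xy.area


def estimate_mission(
    plan: TransectPlan,
    fp: FlightParams,
    constraints: MissionConstraints,
    gcs: Optional[tuple[float, float]] = None,
) -> TransectPlan:
    """Fill flight-time and sortie fields of a plan.

    ``est_flight_time_min`` is transect path length over ground speed;
    ``n_sorties`` is that time split by the airframe's endurance.  With a
    ground-station location ``gcs`` (lat, lon) every waypoint beyond the
    radio range is flagged.
    """
    if not plan.waypoints:
        raise ValueError("plan has no waypoints")
    time_min = plan.total_path_length_km / fp.S * 60.0
    n_sorties = max(1, math.ceil(time_min / constraints.endurance_min - 1e-9))
    out_of_range: list[int] = []
    if gcs is not None:
        gcs_lat, gcs_lon = gcs
        gx, gy = plan.projection.to_xy(gcs_lon, gcs_lat)
        for i, (lon, lat) in enumerate(plan.waypoints):
            x, y = plan.projection.to_xy(lon, lat)
            if math.hypot(x - gx, y - gy) > constraints.max_range_km * 1000.0:
                out_of_range.append(i)
    return replace(plan, est_flight_time_min=time_min, n_sorties=n_sorties,
                   out_of_range_waypoints=tuple(out_of_range))


def feasibility_report(
    plan: TransectPlan,
    fp: FlightParams,
    constraints: MissionConstraints,
    wind_kmh: float,
    rain: bool = False,
    high_humidity: bool = False,
    thick_forest: bool = False,
    populated_area: bool = False,
) -> dict:
    """Structured pass/warn/fail feasibility check for a planned mission.

    Hard checks: wind against the airframe's limit, waypoints against radio
    range.  Soft checks (warn): altitude outside the recommended band,
    missions needing more than one sortie.  The qualitative flags (rain,
    humidity, forest, population) surface as advisories.
    """
    if plan.est_flight_time_min is None:
        plan = estimate_mission(plan, fp, constraints)
    lo, hi = constraints.altitude_band
    checks = {
        "wind": "pass" if wind_kmh < constraints.wind_limit_kmh else "fail",
        "altitude_band": "pass" if lo <= plan.h_agl_m <= hi else "warn",
        "range": "fail" if plan.out_of_range_waypoints else "pass",
        "endurance": "pass" if plan.n_sorties == 1 else "warn",
    }
    advisories = []
    if rain:
        checks["rain"] = "fail"  # electronics and low-light imagery
    if high_humidity:
        advisories.append("high humidity degrades visual and thermal contrast")
    if thick_forest:
        advisories.append("thick forest canopy hampers target detection")
    if populated_area:
        advisories.append("populated areas raise safety and discretion concerns")
    overall = ("fail" if "fail" in checks.values()
               else "warn" if "warn" in checks.values() else "pass")
    return {
        "checks": checks,
        "advisories": advisories,
        "overall": overall,
        "est_flight_time_min": plan.est_flight_time_min,
        "n_sorties": plan.n_sorties,
    }


# ---------------------------------------------------------------------------
# output helpers

def plan_to_geojson(plan: TransectPlan) -> dict:
    """Serpentine waypoint track as a GeoJSON Feature (LineString, WGS84)."""
    return {
        "type": "Feature",
        "geometry": {"type": "LineString",
                     "coordinates": [list(wp) for wp in plan.waypoints]},
        "properties": {
            "area": plan.area_name,
            "swath_m": plan.swath_m,
            "line_spacing_m": plan.line_spacing_m,
            "sidelap_pct": plan.sidelap_pct,
            "heading_deg": plan.heading_deg,
            "h_agl_m": plan.h_agl_m,
            "total_path_length_km": plan.total_path_length_km,
            "n_transects": plan.n_transects,
            "n_turns": plan.n_turns,
            "est_flight_time_min": plan.est_flight_time_min,
            "n_sorties": plan.n_sorties,
        },
    }


def plan_waypoints_csv(plan: TransectPlan) -> str:
    """Waypoint list as CSV text (index, lat, lon, agl_m)."""
    lines = ["index,lat,lon,agl_m"]
    for i, (lon, lat) in enumerate(plan.waypoints):
        lines.append(f"{i},{lat:.6f},{lon:.6f},{plan.h_agl_m:.1f}")
    return "\n".join(lines) + "\n"
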