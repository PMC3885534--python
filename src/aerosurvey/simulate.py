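"""Synthetic landscapes, flights and detections for end-to-end testing.

No public archive of anti-poaching survey flights exists, so the simulator
manufactures the whole chain the other modules consume: a habitat mosaic of
forest and grassland with fence lines along the boundary, ground-truth
targets (rhinoceros at a configurable density, people optionally clustered
near the fences where intrusions concentrate), a 10 Hz GPS + barometric
flight log flown along a transect plan, camera trigger events at the frame
rate, and probabilistic detections graded through the image-quality rubric.

Every stochastic step draws from a single seeded generator, so a run is
fully reproducible from its seed.  By default no false positives are
generated; a rate parameter exists for robustness experiments (thermal
imagery produces contrasting but diffuse blobs that invite them).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box
from shapely import STRtree

from .cameras import CameraModel, FlightParams, KMH_TO_MS
from .detections import (Observation, QualityClass, classify_quality,
                         confirm_detection)
from .georef import FlightLog, GeoFootprint, ImageEvent
from .planning import SurveyArea, TransectPlan
from .projection import LocalTransverseMercator

#: default anchor for synthetic geography (northern KwaZulu-Natal)
DEFAULT_ANCHOR = (-28.2, 31.95)
#: reference rhinoceros density: one animal per 200 ha
RHINO_HA_PER_ANIMAL = 200.0
GPS_HZ = 10.0
DEFAULT_START = _dt.datetime(2012, 8, 15, 9, 0, 0)


@dataclass(frozen=True)
class SyntheticLandscape:
    """A square habitat mosaic with fence lines along its boundary.

    Geometry lives in a local metric frame (metres, origin at the anchor);
    ``projection`` converts to WGS84.  ``cells`` is an (ny, nx) bool array,
    True = forest.
    """

    extent: Polygon
    cells: np.ndarray
    cell_m: float
    fences: LineString
    seed: int
    projection: LocalTransverseMercator

    @property
    def forest_fraction(self) -> float:
        return float(self.cells.mean())

    @property
    def area_ha(self) -> float:
        return self.extent.area / 1e4

    def habitat_at(self, x: float, y: float) -> str:
        ny, nx = self.cells.shape
        j = min(int(x // self.cell_m), nx - 1)
        i = min(int(y // self.cell_m), ny - 1)
        return "forest" if self.cells[i, j] else "grassland"

    def habitat_patches(self) -> list[tuple[Polygon, str]]:
        """Cell polygons with their habitat label (metric frame)."""
        ny, nx = self.cells.shape
        out = []
        for i in range(ny):
            for j in range(nx):
                cell = box(j * self.cell_m, i * self.cell_m,
                           (j + 1) * self.cell_m, (i + 1) * self.cell_m)
                out.append((cell, "forest" if self.cells[i, j] else "grassland"))
        return out

    def survey_area(self, name: str = "synthetic") -> SurveyArea:
        return SurveyArea(polygon=self.projection.unproject_geometry(self.extent),
                          name=name)


def generate_landscape(extent_ha: float, forest_fraction: float, seed: int,
                       cell_m: float = 100.0,
                       anchor: tuple[float, float] = DEFAULT_ANCHOR) -> SyntheticLandscape:
    """Square landscape of ``extent_ha`` with a forest/grassland cell mosaic.

    The forest-cell count is an exact quota (``round(fraction * n_cells)``),
    so the realized fraction differs from the request only by rounding; cell
    placement is drawn from the seed.
    """
    if extent_ha <= 0:
        raise ValueError("extent_ha must be positive")
    if not 0.0 <= forest_fraction <= 1.0:
        raise ValueError("forest_fraction must be in [0, 1]")
    side = math.sqrt(extent_ha * 1e4)
    n = max(1, round(side / cell_m))
    cell = side / n
    rng = np.random.default_rng(seed)
    n_forest = round(forest_fraction * n * n)
    flat = np.zeros(n * n, dtype=bool)
    flat[rng.choice(n * n, size=n_forest, replace=False)] = True
    extent = box(0.0, 0.0, side, side)
    return SyntheticLandscape(
        extent=extent,
        cells=flat.reshape(n, n),
        cell_m=cell,
        fences=LineString(extent.exterior.coords),
        seed=seed,
        projection=LocalTransverseMercator(lat0=anchor[0], lon0=anchor[1]),
    )


def place_targets(landscape: SyntheticLandscape,
                  n_rhino: Optional[int] = None,
                  n_people: int = 0,
                  seed: int = 0,
                  people_near_fences: bool = True,
                  fence_band_m: float = 300.0) -> pd.DataFrame:
    """Ground-truth target placements.

    ``n_rhino`` defaults to the reference density of one animal per 200 ha.
    Rhinoceros are placed uniformly over the extent; people cluster within
    ``fence_band_m`` of the boundary fence when ``people_near_fences`` (the
    usual intrusion pattern: entry near roads, trails and fence lines) and
    are labelled "mixed" habitat there.
    """
    if n_rhino is None:
        n_rhino = round(landscape.area_ha / RHINO_HA_PER_ANIMAL)
    if n_rhino < 0 or n_people < 0:
        raise ValueError("target counts must be >= 0")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = landscape.extent.bounds
    rows = []
    for i in range(n_rhino):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        rows.append(("rhino_%03d" % i, "rhinoceros", x, y,
                     landscape.habitat_at(x, y)))
    for i in range(n_people):
        while True:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            d = landscape.fences.distance(Point(x, y))
            if not people_near_fences or d <= fence_band_m:
                break
        habitat = "mixed" if (people_near_fences and d <= fence_band_m) \
            else landscape.habitat_at(x, y)
        rows.append(("person_%03d" % i, "people", x, y, habitat))
    df = pd.DataFrame(rows, columns=["target_id", "kind", "x", "y", "habitat"])
    if len(df):
        lon, lat = landscape.projection.to_lonlat(df["x"].to_numpy(),
                                                  df["y"].to_numpy())
        df["lon"], df["lat"] = lon, lat
    else:
        df["lon"] = df["lat"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# flight simulation

def simulate_flight(plan: TransectPlan, fp: FlightParams, camera: CameraModel,
                    seed: int = 0, jitter_m: float = 0.0,
                    start_time: _dt.datetime = DEFAULT_START,
                    ) -> tuple[FlightLog, list[ImageEvent]]:
    """Fly a transect plan and emit the 10 Hz log plus camera events.

    The aircraft follows the serpentine path (transects plus straight
    connecting legs) at constant ground speed, logging fixes at 10 Hz with
    optional Gaussian cross-track jitter; the camera fires at its frame rate
    throughout the flight.  Timestamps are strictly increasing from
    ``start_time`` (local clock).
    """
    rng = np.random.default_rng(seed)
    # full polyline: transect segments joined by connector legs
    coords: list[tuple[float, float]] = []
    for seg in plan.transects_xy:
        coords.extend(seg)
    path = LineString(coords)
    total_m = path.length
    v = fp.speed_ms
    duration_s = total_m / v
    n_fix = int(math.floor(duration_s * GPS_HZ)) + 1
    t_s = np.arange(n_fix) / GPS_HZ
    dist = v * t_s

    pts = [path.interpolate(d) for d in dist]
    xy = np.array([[p.x, p.y] for p in pts])
    # course from forward differences along the path
    ahead = np.array([[p.x, p.y] for p in
                      (path.interpolate(min(d + 1.0, total_m)) for d in dist)])
    delta = ahead - xy
    delta[-1] = delta[-2] if n_fix > 1 else [0.0, 1.0]
    course = np.degrees(np.arctan2(delta[:, 0], delta[:, 1])) % 360.0
    if jitter_m > 0:
        theta = np.radians(course)
        across = np.stack([np.cos(theta), -np.sin(theta)], axis=1)
        xy = xy + across * rng.normal(0.0, jitter_m, size=n_fix)[:, None]

    lon, lat = plan.projection.to_lonlat(xy[:, 0], xy[:, 1])
    times = pd.Timestamp(start_time) + pd.to_timedelta(t_s, unit="s")
    log = FlightLog(records=pd.DataFrame({
        "time": times, "lat": lat, "lon": lon,
        "alt_agl_m": np.full(n_fix, fp.h),
        "course_deg": course,
        "speed_kmh": np.full(n_fix, fp.S),
    }))

    n_events = int(math.floor(duration_s * camera.fps)) + 1
    ev_t = np.arange(n_events) / camera.fps
    events = [ImageEvent(timestamp=start_time + _dt.timedelta(seconds=float(s)),
                         camera=camera, image_id=f"IMG_{i:05d}")
              for i, s in enumerate(ev_t)]
    return log, events


# ---------------------------------------------------------------------------
# detection model

_CAMERA_KINDS = ("still_photo", "thermal_video", "visual_video")


@dataclass(frozen=True)
class DetectionModel:
    """Per-camera/period/habitat detection probabilities.

    Probabilities factor as ``base[camera] * period_factor * habitat_factor``
    clipped to [0, 1], and drop to zero above the camera's maximum effective
    altitude.  The defaults are qualitative: visual cameras work best
    morning-to-midday and poorly at night, the thermal camera best in the
    morning and at night when ground contrast is high, and forest hides
    targets that open grassland or fence corridors reveal.  They are
    documented defaults for simulation, not field estimates.
    """

    base: dict = field(default_factory=lambda: {
        "still_photo": 0.9, "thermal_video": 0.5, "visual_video": 0.7})
    period_factor: dict = field(default_factory=lambda: {
        "still_photo": {"morning": 1.0, "midday": 1.0, "evening": 0.6, "night": 0.05},
        "visual_video": {"morning": 1.0, "midday": 1.0, "evening": 0.6, "night": 0.05},
        "thermal_video": {"morning": 1.0, "midday": 0.5, "evening": 0.5, "night": 0.9},
    })
    habitat_factor: dict = field(default_factory=lambda: {
        "grassland": 1.0, "mixed": 1.0, "forest": 0.6})
    max_effective_alt_m: dict = field(default_factory=lambda: {
        "still_photo": 260.0, "thermal_video": 155.0, "visual_video": 50.0})
    quality_probs: tuple = (0.3, 0.45, 0.25)  # high, medium, low
    false_positive_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.quality_probs) - 1.0) > 1e-9:
            raise ValueError("quality_probs must sum to 1")
        for cam, p in self.base.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"base probability for {cam} outside [0, 1]")

    def probability(self, camera: str, period: str, habitat: str,
                    h_agl_m: float) -> float:
        if h_agl_m > self.max_effective_alt_m.get(camera, math.inf):
            return 0.0
        p = (self.base[camera]
             * self.period_factor[camera].get(period, 0.5)
             * self.habitat_factor.get(habitat, 1.0))
        return min(max(p, 0.0), 1.0)

    @classmethod
    def uniform(cls, p: float, max_alt_m: float = math.inf) -> "DetectionModel":
        """Flat model: the same probability everywhere (for experiments)."""
        return cls(base={c: p for c in _CAMERA_KINDS},
                   period_factor={c: {per: 1.0 for per in
                                      ("morning", "midday", "evening", "night")}
                                  for c in _CAMERA_KINDS},
                   habitat_factor={h: 1.0 for h in ("forest", "grassland", "mixed")},
                   max_effective_alt_m={c: max_alt_m for c in _CAMERA_KINDS})


def run_detection(truth: pd.DataFrame, footprints: Sequence[GeoFootprint],
                  model: DetectionModel, camera_kind: str, period: str,
                  seed: int = 0, flight_id: str = "SIM",
                  n_images: int = 3) -> list[Observation]:
    """Probabilistic detection of truth targets covered by footprints.

    A target inside at least one footprint is detected with the model's
    probability (independent Bernoulli per target); detected targets get
    ``n_images`` quality draws and a confirmed/not-confirmed result through
    the image-quality rubric.  Uncovered targets are never detected, and by
    default no false positives are produced.
    """
    if camera_kind not in _CAMERA_KINDS:
        raise ValueError(f"unknown camera kind {camera_kind!r}")
    rng = np.random.default_rng(seed)
    polys = [f.polygon for f in footprints if f.polygon is not None]
    h_of = [f.h_agl_m for f in footprints if f.polygon is not None]
    tree = STRtree(polys) if polys else None
    observations: list[Observation] = []
    for row in truth.itertuples(index=False):
        if tree is None:
            continue
        pt = Point(row.lon, row.lat)
        hits = [i for i in tree.query(pt) if polys[i].covers(pt)]
        if not hits:
            continue
        h = min(h_of[i] for i in hits)
        p = model.probability(camera_kind, period, row.habitat, h)
        if rng.random() >= p:
            continue
        qualities = _draw_qualities(rng, model, n_images)
        result = confirm_detection(qualities)
        confirmed = result == "confirmed"
        observations.append(Observation(
            flight_id=flight_id,
            camera=camera_kind,
            target=row.kind,
            habitat=frozenset([row.habitat]),
            result=result,
            period=period,
            alt_min_m=h if confirmed else None,
            alt_max_m=h if confirmed else None,
        ))
    return observations


def _draw_qualities(rng: np.random.Generator, model: DetectionModel,
                    n: int) -> list[QualityClass]:
    levels = rng.choice(3, size=n, p=model.quality_probs)
    out = []
    for lv in levels:
        if lv == 0:
            out.append(classify_quality(target_identified_first_glance=True))
        elif lv == 1:
            out.append(classify_quality(needs_zoom_or_postprocess=True))
        else:
            out.append(classify_quality(object_detected_only=True))
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience

@dataclass(frozen=True)
class SimResult:
    landscape: SyntheticLandscape
    truth: pd.DataFrame
    plan: TransectPlan
    log: FlightLog
    events: list
    footprints: list
    observations: list


def simulate_survey(extent_ha: float, forest_fraction: float,
                    camera: CameraModel, camera_kind: str,
                    fp: FlightParams, sidelap: float, period: str,
                    seed: int, n_people: int = 5,
                    model: Optional[DetectionModel] = None,
                    jitter_m: float = 0.0) -> SimResult:
    """Landscape -> targets -> plan -> flight -> georeference -> detect."""
    from .georef import georeference_events
    from .planning import plan_lawnmower

    model = model or DetectionModel()
    rng = np.random.default_rng(seed)
    s_land, s_targ, s_fly, s_det = rng.integers(0, 2**31 - 1, size=4)
    landscape = generate_landscape(extent_ha, forest_fraction, int(s_land))
    truth = place_targets(landscape, n_people=n_people, seed=int(s_targ))
    plan = plan_lawnmower(landscape.survey_area(), camera, fp.h, sidelap)
    log, events = simulate_flight(plan, fp, camera, seed=int(s_fly),
                                  jitter_m=jitter_m)
    footprints = georeference_events(log, events)
    observations = run_detection(truth, footprints, model, camera_kind,
                                 period, seed=int(s_det))
    return SimResult(landscape=landscape, truth=truth, plan=plan, log=log,
                     events=events, footprints=footprints,
                     observations=observations)
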