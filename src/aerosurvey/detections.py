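"""Observation schema and classification rubrics for detection flights.

A survey flight passes over candidate targets (rhinoceros, people acting as
poachers, fence lines) and every pass yields imagery that a reviewer grades.
This module encodes the bookkeeping: image-quality grading, the
confirmed/not-confirmed rule, habitat and time-of-day classification, and
summary tables over collections of :class:`Observation` records.  The
reference flight-campaign results ship as a CSV fixture loadable with
:func:`load_table2`.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

CAMERAS = ("still_photo", "thermal_video", "visual_video")
PERIODS = ("morning", "midday", "evening", "night")
TARGETS = ("rhinoceros", "people", "fence")
HABITATS = ("forest", "grassland", "mixed")
RESULTS = ("confirmed", "not_confirmed")

#: time-of-day bins (inclusive bounds, minute resolution, local time)
PERIOD_BINS = {
    "morning": (_dt.time(7, 0), _dt.time(10, 15)),
    "midday": (_dt.time(10, 16), _dt.time(14, 0)),
    "evening": (_dt.time(14, 1), _dt.time(17, 45)),
    "night": (_dt.time(17, 46), _dt.time(20, 0)),
}


@dataclass(frozen=True)
class Observation:
    """One target-detection record from a survey flight.

    ``habitat`` is a frozenset because a single target can straddle habitat
    classes (e.g. a fence line crossing grassland and a farm boundary).
    ``alt_min_m``/``alt_max_m`` are the lowest/highest altitudes AGL at which
    the target was confirmed; equal when it was located once, absent when it
    was never confirmed.
    """

    flight_id: str
    camera: str
    target: str
    habitat: frozenset
    result: str
    period: Optional[str] = None
    time_start: Optional[_dt.time] = None
    time_end: Optional[_dt.time] = None
    alt_min_m: Optional[float] = None
    alt_max_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.camera not in CAMERAS:
            raise ValueError(f"unknown camera {self.camera!r}")
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.result not in RESULTS:
            raise ValueError(f"unknown result {self.result!r}")
        if not self.habitat or not set(self.habitat) <= set(HABITATS):
            raise ValueError(f"invalid habitat set {set(self.habitat)!r}")
        has_min, has_max = self.alt_min_m is not None, self.alt_max_m is not None
        if self.result == "confirmed":
            if not (has_min or has_max):
                raise ValueError("confirmed observation needs an altitude")
        elif has_min or has_max:
            raise ValueError("not-confirmed observation cannot carry altitudes")
        if has_min and has_max and self.alt_min_m > self.alt_max_m:
            raise ValueError("alt_min_m must be <= alt_max_m")


@dataclass(frozen=True)
class QualityClass:
    """Image-quality grade with the evidence flags that imply it."""

    level: str  # high | medium | low
    target_identified_first_glance: bool = False
    needs_zoom_or_postprocess: bool = False
    fence_poles_visible: bool = False
    fence_wires_visible: bool = False
    object_detected_only: bool = False


def parse_clock_time(t) -> _dt.time:
    if isinstance(t, _dt.time):
        return t
    if isinstance(t, _dt.datetime):
        return t.time()
    if isinstance(t, str):
        for fmt in ("%H:%M:%S", "%H:%M"):
            try:
                return _dt.datetime.strptime(t, fmt).time()
            except ValueError:
                continue
    raise ValueError(f"malformed clock time: {t!r}")


def classify_time_period(t) -> str:
    """Bin a local clock time into morning/midday/evening/night.

    Bin edges are inclusive at minute resolution (seconds are truncated);
    times outside 07:00-20:00 return ``"unclassified"``.
    """
    tt = parse_clock_time(t)
    tt = _dt.time(tt.hour, tt.minute)
    for period, (lo, hi) in PERIOD_BINS.items():
        if lo <= tt <= hi:
            return period
    return "unclassified"


def classify_habitat(cover_fraction: float, on_farm_boundary: bool = False) -> str:
    """Habitat class from vegetation cover within 100 m of the target.

    Farm-boundary locations are "mixed" regardless of cover: the fence
    maintenance trails keep them open from a detectability standpoint.
    Otherwise forest iff cover strictly exceeds 75 %.
    """
    if not 0.0 <= cover_fraction <= 1.0:
        raise ValueError("cover_fraction must be in [0, 1]")
    if on_farm_boundary:
        return "mixed"
    return "forest" if cover_fraction > 0.75 else "grassland"


def classify_quality(
    *,
    target_identified_first_glance: bool = False,
    needs_zoom_or_postprocess: bool = False,
    fence_poles_visible: bool = False,
    fence_wires_visible: bool = False,
    object_detected_only: bool = False,
) -> QualityClass:
    """Grade one image or video frame as high / medium / low quality.

    High: the target is identified at first glance (for fences: both poles
    and wires resolved).  Medium: identification needs zooming, slow-motion
    review or post-processing (fences: poles without wires).  Low: an object
    is detected but cannot be identified (fences: trajectory only).
    """
    if fence_wires_visible and not fence_poles_visible:
        raise ValueError("fence wires visible implies poles visible")
    if object_detected_only and (target_identified_first_glance
                                 or needs_zoom_or_postprocess
                                 or fence_wires_visible):
        raise ValueError("object_detected_only contradicts identification flags")
    if target_identified_first_glance and needs_zoom_or_postprocess:
        raise ValueError("first-glance identification contradicts needing zoom")

    flags = dict(
        target_identified_first_glance=target_identified_first_glance,
        needs_zoom_or_postprocess=needs_zoom_or_postprocess,
        fence_poles_visible=fence_poles_visible,
        fence_wires_visible=fence_wires_visible,
        object_detected_only=object_detected_only,
    )
    if target_identified_first_glance or fence_wires_visible:
        return QualityClass("high", **flags)
    if needs_zoom_or_postprocess or fence_poles_visible:
        return QualityClass("medium", **flags)
    if object_detected_only:
        return QualityClass("low", **flags)
    raise ValueError("no evidence flags set; cannot grade image")


def confirm_detection(qualities: Sequence[QualityClass]) -> str:
    """Confirmed iff the target appears in >=1 high- or medium-quality image."""
    levels = {q.level for q in qualities}
    return "confirmed" if levels & {"high", "medium"} else "not_confirmed"


# ---------------------------------------------------------------------------
# summaries

def observations_to_frame(observations: Iterable[Observation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append({
            "flight_id": o.flight_id,
            "camera": o.camera,
            "period": o.period,
            "time_start": o.time_start.strftime("%H:%M") if o.time_start else None,
            "time_end": o.time_end.strftime("%H:%M") if o.time_end else None,
            "target": o.target,
            "habitat": "|".join(sorted(o.habitat)),
            "result": o.result,
            "alt_min_m": o.alt_min_m,
            "alt_max_m": o.alt_max_m,
        })
    return pd.DataFrame(rows, columns=["flight_id", "camera", "period", "time_start",
                                       "time_end", "target", "habitat", "result",
                                       "alt_min_m", "alt_max_m"])


def summarize(observations, group_by: Sequence[str] = ("camera", "target")) -> pd.DataFrame:
    """Per-group detection summary.

    Returns, per group, the number of confirmed and not-confirmed records and
    the extreme confirmed altitudes (min of ``alt_min_m``, max of
    ``alt_max_m``).  Grouping by ``habitat`` explodes multi-habitat records,
    so such a row counts once per habitat class it touches; any other
    grouping counts each record exactly once.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations.copy()
    else:
        df = observations_to_frame(observations)
    if df.empty:
        return pd.DataFrame(columns=[*group_by, "n_confirmed", "n_not_confirmed",
                                     "alt_min_m", "alt_max_m"])
    bad = set(group_by) - set(df.columns)
    if bad:
        raise ValueError(f"unknown group_by fields: {sorted(bad)}")
    if "habitat" in group_by:
        df = df.assign(habitat=df["habitat"].str.split("|")).explode("habitat")

    def _agg(g: pd.DataFrame) -> pd.Series:
        conf = g[g["result"] == "confirmed"]
        return pd.Series({
            "n_confirmed": len(conf),
            "n_not_confirmed": int((g["result"] == "not_confirmed").sum()),
            "alt_min_m": conf["alt_min_m"].min(),
            "alt_max_m": conf["alt_max_m"].max(),
        })

    out = (df.groupby(list(group_by), dropna=False)
             .apply(_agg, include_groups=False)
             .reset_index())
    out["n_confirmed"] = out["n_confirmed"].astype(int)
    out["n_not_confirmed"] = out["n_not_confirmed"].astype(int)
    return out


# ---------------------------------------------------------------------------
# reference fixture

def load_table2() -> pd.DataFrame:
    """Load the packaged reference flight-results table as a DataFrame."""
    with resources.files("aerosurvey.data").joinpath("table2_flights.csv").open() as fh:
        return pd.read_csv(fh, dtype={"flight_id": str})


def table2_observations() -> list[Observation]:
    """The reference flight results as validated :class:`Observation` records."""
    df = load_table2()
    obs = []
    for row in df.itertuples(index=False):
        obs.append(Observation(
            flight_id=row.flight_id,
            camera=row.camera,
            period=row.period,
            time_start=parse_clock_time(row.time_start),
            time_end=parse_clock_time(row.time_end),
            target=row.target,
            habitat=frozenset(row.habitat.split("|")),
            result=row.result,
            alt_min_m=None if pd.isna(row.alt_min_m) else float(row.alt_min_m),
            alt_max_m=None if pd.isna(row.alt_max_m) else float(row.alt_max_m),
        ))
    return obs


def read_observations_csv(path) -> pd.DataFrame:
    """Read an observations CSV in the fixture's column layout."""
    return pd.read_csv(path, dtype={"flight_id": str})
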