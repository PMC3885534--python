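"""Imaging geometry for small-RPAS survey cameras.

Pinhole similar-triangle relations tie a camera's sensor constants to ground
footprint size, along-track image overlap, ground resolution (GSD) and the
areal coverage rate of a survey flight:

* footprint along/across track:  ``L = (dv/f) * h``,  ``W = (dh/f) * h``
* along-track overlap:           ``O = 100 * (1 - S / (P * (dv/f) * h))``
* ground resolution:             ``R = c_res * h``   (linear in altitude)
* coverage rate:                 ``A = S_kmh * (dh/f) * h / 10``  [ha/h]

where ``dv``/``dh`` are the sensor's vertical/horizontal dimensions (mm),
``f`` the focal length (mm), ``P`` the frame rate (1/s), ``h`` altitude AGL
(m) and ``S`` ground speed (m/s inside the overlap formula, km/h at the
interface).  Video cameras specified by a diagonal field of view instead of
sensor dimensions get equivalent per-axis constants from
``2 * tan(fov_axis / 2)`` with the diagonal split in pixel proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

KMH_TO_MS = 1000.0 / 3600.0


@dataclass(frozen=True)
class CameraModel:
    """A survey camera described by sensor constants or field of view.

    Exactly one of the two descriptions must be supplied:

    * ``dv_mm``, ``dh_mm``, ``f_mm`` — physical sensor and optics, or
    * ``fov_diag_deg`` (with pixel counts) — for video cameras whose spec
      sheet gives a diagonal field of view.

    ``res_cm_per_m`` is an optional empirically calibrated ground-resolution
    constant (cm of ground per m of altitude); when absent the GSD is derived
    from footprint size and pixel counts.
    """

    name: str
    dv_mm: Optional[float] = None
    dh_mm: Optional[float] = None
    f_mm: Optional[float] = None
    fps: float = 1.0
    px_h: Optional[int] = None
    px_v: Optional[int] = None
    fov_diag_deg: Optional[float] = None
    mount_depression_deg: float = 90.0  # 90 = nadir
    res_cm_per_m: Optional[float] = None

    def __post_init__(self) -> None:
        sensor = (self.dv_mm, self.dh_mm, self.f_mm)
        has_sensor = all(v is not None for v in sensor)
        if any(v is not None for v in sensor) and not has_sensor:
            raise ValueError("dv_mm, dh_mm and f_mm must be given together")
        if has_sensor == (self.fov_diag_deg is not None):
            raise ValueError(
                "exactly one of (dv_mm, dh_mm, f_mm) or fov_diag_deg must be provided")
        if has_sensor:
            for nm in ("dv_mm", "dh_mm", "f_mm"):
                if getattr(self, nm) <= 0:
                    raise ValueError(f"{nm} must be positive")
        else:
            if not 0 < self.fov_diag_deg < 180:
                raise ValueError("fov_diag_deg must be in (0, 180)")
            if self.px_h is None or self.px_v is None:
                raise ValueError("fov-specified cameras need px_h and px_v "
                                 "to split the diagonal field of view")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 < self.mount_depression_deg <= 90:
            raise ValueError("mount_depression_deg must be in (0, 90]")

    # per-axis footprint constants (metres of ground per metre of altitude) --
    @property
    def k_along(self) -> float:
        """Along-track footprint per metre AGL: dv/f, or 2*tan(fov_v/2)."""
        if self.dv_mm is not None:
            return self.dv_mm / self.f_mm
        return 2.0 * math.tan(self._half_angle(self.px_v))

    @property
    def k_across(self) -> float:
        """Across-track (swath) footprint per metre AGL: dh/f, or 2*tan(fov_h/2)."""
        if self.dh_mm is not None:
            return self.dh_mm / self.f_mm
        return 2.0 * math.tan(self._half_angle(self.px_h))

    def _half_angle(self, px_axis: int) -> float:
        # split tan of the half diagonal in pixel proportion, so per-axis GSD
        # comes out identical on both axes
        diag_px = math.hypot(self.px_h, self.px_v)
        tan_half_diag = math.tan(math.radians(self.fov_diag_deg) / 2.0)
        return math.atan(px_axis / diag_px * tan_half_diag)

    @property
    def is_nadir(self) -> bool:
        return self.mount_depression_deg == 90.0


@dataclass(frozen=True)
class FlightParams:
    """Flight altitude above ground level (m) and ground speed (km/h)."""

    h: float
    S: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("altitude h must be >= 0")
        if self.S <= 0:
            raise ValueError("speed S must be positive")

    @property
    def speed_ms(self) -> float:
        return self.S * KMH_TO_MS


@dataclass(frozen=True)
class FootprintDims:
    along_track_m: float
    across_track_m: float
    gsd_cm: Optional[float]


def footprint_dims(camera: CameraModel, h: float) -> FootprintDims:
    """Ground footprint of one exposure at altitude ``h`` m AGL."""
    if h < 0:
        raise ValueError("altitude h must be >= 0")
    return FootprintDims(
        along_track_m=camera.k_along * h,
        across_track_m=camera.k_across * h,
        gsd_cm=ground_resolution(camera, h),
    )


def along_track_overlap(camera: CameraModel, fp: FlightParams) -> float:
    """Percent overlap between consecutive exposures, in [0, 100).

    The aircraft advances ``S / P`` metres between exposures; overlap is the
    fraction of the along-track footprint not consumed by that advance.  At
    ``h = 0`` the footprint is a point and overlap is defined as 0 %, and a
    faster-than-footprint advance clamps to 0 rather than going negative
    (coverage gaps are a planning concern, reported separately).
    """
    footprint = camera.k_along * fp.h
    if footprint <= 0.0:
        return 0.0
    overlap = 100.0 * (1.0 - fp.speed_ms / (camera.fps * footprint))
    return min(max(overlap, 0.0), 100.0 - 1e-12)


def ground_resolution(camera: CameraModel, h: float) -> Optional[float]:
    """Ground resolution in cm at altitude ``h`` m AGL; linear in altitude.

    Uses the camera's calibrated ``res_cm_per_m`` constant when present,
    otherwise footprint size divided by pixel count.  ``None`` when the
    camera carries neither.
    """
    if h < 0:
        raise ValueError("altitude h must be >= 0")
    if camera.res_cm_per_m is not None:
        return camera.res_cm_per_m * h
    if camera.px_v is not None and camera.px_h is not None:
        per_px = 0.5 * (camera.k_along / camera.px_v + camera.k_across / camera.px_h)
        return 100.0 * per_px * h
    return None


def coverage_rate(camera: CameraModel, fp: FlightParams) -> float:
    """Area imaged per hour of straight flight, ha/h.

    Swath width (m) times distance flown in one hour (km), i.e.
    ``A = S_kmh * (dh/f) * h / 10``; exactly linear in speed and altitude.
    """
    return fp.S * camera.k_across * fp.h / 10.0


def time_to_cover(area_ha: float, camera: CameraModel, fp: FlightParams) -> float:
    """Gross flight hours to image ``area_ha`` hectares at the given rate.

    Strip-coverage time only: repositioning, battery swaps and data
    processing are excluded.
    """
    if area_ha < 0:
        raise ValueError("area_ha must be >= 0")
    if area_ha == 0:
        return 0.0
    rate = coverage_rate(camera, fp)
    if rate <= 0:
        raise ValueError("coverage rate is zero; cannot cover a positive area")
    return area_ha / rate


# ---------------------------------------------------------------------------
# built-in camera profiles

def _load_builtin_profiles() -> dict:
    text = resources.files("aerosurvey.data").joinpath("profiles.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: CameraModel(name=name, **kw) for name, kw in raw.items()}


_BUILTINS: Optional[dict] = None


def builtin_profiles() -> dict:
    global _BUILTINS
    if _BUILTINS is None:
        _BUILTINS = _load_builtin_profiles()
    return dict(_BUILTINS)


def get_camera(name: str) -> CameraModel:
    """Look up a built-in camera profile by name."""
    profiles = builtin_profiles()
    try:
        return profiles[name]
    except KeyError:
        raise KeyError(f"unknown camera profile {name!r}; "
                       f"available: {sorted(profiles)}") from None


def load_profile(path: str, name: Optional[str] = None) -> CameraModel:
    """Load a camera profile from a YAML key-value file.

    The file either describes one camera (flat mapping) or several (mapping
    of name -> mapping); ``name`` selects one in the latter case.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if name is not None:
        raw = raw[name]
        return CameraModel(name=name, **raw)
    profile_name = raw.pop("name", "custom")
    return CameraModel(name=profile_name, **raw)
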