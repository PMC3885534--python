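"""Local metric map projection for farm-scale survey geometry.

All metric operations (footprints, transect spacing, areas) are done in a
transverse-Mercator frame centred on the working area, then re-expressed in
WGS84 lon/lat.  At the extents involved here (single game farms, tens of km
at most) the spherical form of the projection is accurate to well under a
metre relative to its own inverse and distance/area distortion is negligible,
so no ellipsoidal machinery is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as _shapely_transform

#: mean Earth radius, m (IUGG)
EARTH_RADIUS_M = 6371008.8


@dataclass(frozen=True)
class LocalTransverseMercator:
    """Spherical transverse Mercator tangent at (lat0, lon0).

    ``to_xy`` maps lon/lat degrees to metres east/north of the origin;
    ``to_lonlat`` inverts it.  Both accept scalars or numpy arrays.
    """

    lat0: float
    lon0: float
    radius: float = EARTH_RADIUS_M

    @classmethod
    def centered_on(cls, geometry: BaseGeometry) -> "LocalTransverseMercator":
        c = geometry.centroid
        return cls(lat0=c.y, lon0=c.x)

    @classmethod
    def centered_on_points(cls, lons: Iterable[float], lats: Iterable[float]) -> "LocalTransverseMercator":
        return cls(lat0=float(np.mean(np.asarray(list(lats), dtype=float))),
                   lon0=float(np.mean(np.asarray(list(lons), dtype=float))))

    def to_xy(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = math.radians(self.lat0)
        b = np.cos(phi) * np.sin(lam)
        # Snyder (1987) eq. 8-1, 8-3 for the sphere
        x = 0.5 * self.radius * np.log((1.0 + b) / (1.0 - b))
        y = self.radius * (np.arctan2(np.tan(phi), np.cos(lam)) - phi0)
        return x, y

    def to_lonlat(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        phi0 = math.radians(self.lat0)
        d = y / self.radius + phi0
        lon = self.lon0 + np.degrees(np.arctan2(np.sinh(x / self.radius), np.cos(d)))
        lat = np.degrees(np.arcsin(np.sin(d) / np.cosh(x / self.radius)))
        return lon, lat

    # shapely geometry helpers -------------------------------------------------
    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        """lon/lat geometry -> metric geometry."""
        return _shapely_transform(lambda lon, lat: self.to_xy(lon, lat), geom)

    def unproject_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        """metric geometry -> lon/lat geometry."""
        return _shapely_transform(lambda x, y: self.to_lonlat(x, y), geom)
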