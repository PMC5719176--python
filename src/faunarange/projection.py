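"""Lambert cylindrical equal-area projection on a spherical earth.

All areas in the pipeline are measured in one equal-area plane so that
range polygons from different periods and species are directly comparable
in km^2.  The projection is the cylindrical equal-area case with standard
parallel 0 deg:

    x = R * (lambda - lambda_0) * cos(phi_s)
    y = R * sin(phi) / cos(phi_s)

with R the authalic-like spherical radius (default 6371.0072 km) and
``lambda_0`` the central meridian, by default the centroid longitude of
the study-region border (105 deg E for a China-like region).  On the
sphere the projection is exactly equal-area, so a lon/lat quadrangle maps
to a rectangle of area R^2 * d(lambda) * d(sin phi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform

#: Spherical earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class EqualAreaProjection:
    """Cylindrical equal-area projection with configurable central meridian.

    Parameters
    ----------
    central_meridian : float
        Longitude (degrees) mapped to x = 0.  Geometry within 180 deg of
        this meridian projects without wrap-around.
    standard_parallel : float
        Latitude of true scale, degrees.  0 gives the Lambert form.
    radius_km : float
        Spherical earth radius, km.
    """

    central_meridian: float = 105.0
    standard_parallel: float = 0.0
    radius_km: float = EARTH_RADIUS_KM

    @property
    def crs_tag(self) -> str:
        return (
            f"cea:+lon_0={self.central_meridian}"
            f"+lat_ts={self.standard_parallel}+R={self.radius_km}km"
        )

    def forward(self, lon, lat):
        """Project lon/lat degrees to planar (x, y) in km."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
        dlon = (lon - self.central_meridian + 180.0) % 360.0 - 180.0
        cos_ts = np.cos(np.radians(self.standard_parallel))
        x = self.radius_km * np.radians(dlon) * cos_ts
        y = self.radius_km * np.sin(np.radians(lat)) / cos_ts
        return x, y

    def inverse(self, x, y):
        """Planar (x, y) km back to lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cos_ts = np.cos(np.radians(self.standard_parallel))
        lon = self.central_meridian + np.degrees(x / (self.radius_km * cos_ts))
        sin_lat = y * cos_ts / self.radius_km
        if np.any(np.abs(sin_lat) > 1.0 + 1e-12):
            raise ValueError("y outside projectable range")
        lat = np.degrees(np.arcsin(np.clip(sin_lat, -1.0, 1.0)))
        return lon, lat

    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        """Project a shapely geometry from WGS84 lon/lat to the plane.

        Raises if the geometry spans the antimeridian cut opposite the
        central meridian (longitudes within 1 deg of the cut on both
        sides), since straight planar edges would then be wrong.
        """
        minx, _, maxx, _ = geom.bounds
        if not geom.is_empty:
            dmin = (minx - self.central_meridian + 180.0) % 360.0 - 180.0
            dmax = (maxx - self.central_meridian + 180.0) % 360.0 - 180.0
            if dmin > dmax or abs(dmin) == 180.0 or abs(dmax) == 180.0:
                raise ValueError(
                    "geometry spans the projection's antimeridian cut; "
                    "move the central meridian"
                )
        return transform(lambda lon, lat: self.forward(lon, lat), geom)

    def unproject_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        return transform(lambda x, y: self.inverse(x, y), geom)


def spherical_quad_area_km2(
    lon0: float, lon1: float, lat0: float, lat1: float, radius_km: float = EARTH_RADIUS_KM
) -> float:
    """Closed-form area of a lon/lat quadrangle on the sphere (km^2).

    R^2 * d(lambda) * (sin phi_1 - sin phi_0); the independent check for
    the projection's area preservation.
    """
    dlam = np.radians(lon1 - lon0)
    return float(radius_km**2 * dlam * (np.sin(np.radians(lat1)) - np.sin(np.radians(lat0))))
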