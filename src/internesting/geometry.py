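"""Spherical geometry primitives shared by every pipeline stage.

All distances are great-circle on a sphere of radius ``EARTH_RADIUS_KM``.
Planar work happens in one of two local projections:

* azimuthal equidistant (AEQD) — preserves distance from the projection
  centre; used for movement modelling, where step lengths matter;
* Lambert azimuthal equal-area (LAEA) — preserves area; used for home-range
  polygons, centroids and occupancy grids.

Both are spherical closed forms, adequate at the < 1000 km extents of an
inter-nesting season.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * radius * np.arcsin(np.sqrt(a))


def track_distances_km(lons, lats):
    """Distances between successive points of a path (length n-1)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])


class _LocalProjection:
    """Base for spherical projections centred on (lon0, lat0), in km."""

    def __init__(self, lon0: float, lat0: float, radius: float = EARTH_RADIUS_KM):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.radius = float(radius)
        self._lam0 = np.radians(self.lon0)
        self._phi0 = np.radians(self.lat0)

    def __repr__(self):  # pragma: no cover
        return f"{type(self).__name__}(lon0={self.lon0:.4f}, lat0={self.lat0:.4f})"


class AzimuthalEquidistant(_LocalProjection):
    """Spherical azimuthal equidistant projection (distances from centre exact)."""

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        cos_c = (np.sin(self._phi0) * np.sin(phi)
                 + np.cos(self._phi0) * np.cos(phi) * np.cos(lam - self._lam0))
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k -> 1 as c -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = self.radius * k * np.cos(phi) * np.sin(lam - self._lam0)
        y = self.radius * k * (np.cos(self._phi0) * np.sin(phi)
                               - np.sin(self._phi0) * np.cos(phi) * np.cos(lam - self._lam0))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        c = np.sqrt(x ** 2 + y ** 2)
        safe_c = np.where(c > 1e-12, c, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cos_c * np.sin(self._phi0)
                                + np.where(c > 1e-12, y * sin_c * np.cos(self._phi0) / safe_c, 0.0),
                                -1.0, 1.0))
        lam = self._lam0 + np.arctan2(
            x * sin_c,
            safe_c * np.cos(self._phi0) * cos_c - y * np.sin(self._phi0) * sin_c,
        )
        lam = np.where(c > 1e-12, lam, self._lam0)
        phi = np.where(c > 1e-12, phi, self._phi0)
        return np.degrees(lam), np.degrees(phi)


class LambertAzimuthalEqualArea(_LocalProjection):
    """Spherical Lambert azimuthal equal-area projection (areas exact)."""

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        denom = 1.0 + (np.sin(self._phi0) * np.sin(phi)
                       + np.cos(self._phi0) * np.cos(phi) * np.cos(lam - self._lam0))
        denom = np.maximum(denom, 1e-12)
        kp = np.sqrt(2.0 / denom)
        x = self.radius * kp * np.cos(phi) * np.sin(lam - self._lam0)
        y = self.radius * kp * (np.cos(self._phi0) * np.sin(phi)
                                - np.sin(self._phi0) * np.cos(phi) * np.cos(lam - self._lam0))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius
        rho = np.sqrt(x ** 2 + y ** 2)
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cos_c * np.sin(self._phi0)
                                + np.where(rho > 1e-12, y * sin_c * np.cos(self._phi0) / safe_rho, 0.0),
                                -1.0, 1.0))
        lam = self._lam0 + np.arctan2(
            x * sin_c,
            safe_rho * np.cos(self._phi0) * cos_c - y * np.sin(self._phi0) * sin_c,
        )
        lam = np.where(rho > 1e-12, lam, self._lam0)
        phi = np.where(rho > 1e-12, phi, self._phi0)
        return np.degrees(lam), np.degrees(phi)


def interior_angles_deg(x, y):
    """Interior angle at each middle vertex of a planar path, in degrees.

    Angle between the incoming segment reversed and the outgoing segment:
    0 deg is an out-and-back spike, 180 deg a straight continuation.
    Vertices adjacent to a zero-length segment get NaN.
    Returns an array of length n-2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx1, vy1 = x[:-2] - x[1:-1], y[:-2] - y[1:-1]   # back toward previous point
    vx2, vy2 = x[2:] - x[1:-1], y[2:] - y[1:-1]     # forward to next point
    n1 = np.hypot(vx1, vy1)
    n2 = np.hypot(vx2, vy2)
    ok = (n1 > 0) & (n2 > 0)
    cosang = np.where(ok, (vx1 * vx2 + vy1 * vy2) / np.where(ok, n1 * n2, 1.0), np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
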