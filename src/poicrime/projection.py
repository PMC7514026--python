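"""Planar coordinate reference systems for crime/POI point data.

The model works entirely in planar metres (Euclidean kernel distances are
only meaningful in a metric projection).  Open police data carries WGS84
longitude/latitude, so a projection is applied at read time.  Two CRS
implementations are provided:

* :class:`BritishNationalGrid` — transverse Mercator on the Airy 1830
  ellipsoid with a 7-parameter Helmert datum shift between WGS84 and
  OSGB36, matching the National Grid convention of UK mapping data to
  within a few metres (the Helmert shift is the standard single-transform
  approximation).
* :class:`LocalEquirectangular` — a trivial local tangent-plane projection
  around a configurable origin, useful for synthetic cities and for data
  outside Great Britain.

Both support forward (lon/lat -> x/y metres) and inverse transforms, so
synthetic-city CSV writers can round-trip through the same I/O path that
real data uses.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BritishNationalGrid",
    "LocalEquirectangular",
    "get_crs",
]

# Airy 1830 ellipsoid and National Grid transverse Mercator constants
_AIRY_A = 6377563.396
_AIRY_B = 6356256.909
_WGS_A = 6378137.0
_WGS_B = 6356752.3142
_F0 = 0.9996012717          # central-meridian scale factor
_LAT0 = np.radians(49.0)    # true origin 49N 2W
_LON0 = np.radians(-2.0)
_E0 = 400000.0              # false easting/northing
_N0 = -100000.0

# Helmert parameters WGS84 -> OSGB36 (tx,ty,tz metres; s ppm; rx,ry,rz arcsec)
_HELMERT = (-446.448, 125.157, -542.060, 20.4894,
            -0.1502, -0.2470, -0.8421)


def _geodetic_to_cartesian(lon, lat, a, b):
    e2 = 1 - (b / a) ** 2
    nu = a / np.sqrt(1 - e2 * np.sin(lat) ** 2)
    x = nu * np.cos(lat) * np.cos(lon)
    y = nu * np.cos(lat) * np.sin(lon)
    z = nu * (1 - e2) * np.sin(lat)
    return x, y, z


def _cartesian_to_geodetic(x, y, z, a, b):
    e2 = 1 - (b / a) ** 2
    p = np.hypot(x, y)
    lat = np.arctan2(z, p * (1 - e2))
    for _ in range(8):  # converges to sub-mm in a few iterations
        nu = a / np.sqrt(1 - e2 * np.sin(lat) ** 2)
        lat = np.arctan2(z + e2 * nu * np.sin(lat), p)
    lon = np.arctan2(y, x)
    return lon, lat


def _helmert(x, y, z, params, inverse=False):
    tx, ty, tz, s_ppm, rx_s, ry_s, rz_s = params
    sign = -1.0 if inverse else 1.0
    tx, ty, tz = sign * tx, sign * ty, sign * tz
    s = sign * s_ppm * 1e-6
    rx = sign * np.radians(rx_s / 3600.0)
    ry = sign * np.radians(ry_s / 3600.0)
    rz = sign * np.radians(rz_s / 3600.0)
    xp = tx + (1 + s) * x - rz * y + ry * z
    yp = ty + rz * x + (1 + s) * y - rx * z
    zp = tz - ry * x + rx * y + (1 + s) * z
    return xp, yp, zp


def _tm_forward(lon, lat):
    """Transverse Mercator, OSGB36 lon/lat (radians) -> easting, northing."""
    a, b = _AIRY_A, _AIRY_B
    e2 = 1 - (b / a) ** 2
    n = (a - b) / (a + b)
    sin_lat, cos_lat, tan_lat = np.sin(lat), np.cos(lat), np.tan(lat)
    nu = a * _F0 / np.sqrt(1 - e2 * sin_lat ** 2)
    rho = a * _F0 * (1 - e2) * (1 - e2 * sin_lat ** 2) ** -1.5
    eta2 = nu / rho - 1

    dlat, slat = lat - _LAT0, lat + _LAT0
    M = b * _F0 * (
        (1 + n + 1.25 * n ** 2 + 1.25 * n ** 3) * dlat
        - (3 * n + 3 * n ** 2 + 2.625 * n ** 3) * np.sin(dlat) * np.cos(slat)
        + (1.875 * n ** 2 + 1.875 * n ** 3) * np.sin(2 * dlat) * np.cos(2 * slat)
        - (35 / 24) * n ** 3 * np.sin(3 * dlat) * np.cos(3 * slat)
    )

    I = M + _N0
    II = nu / 2 * sin_lat * cos_lat
    III = nu / 24 * sin_lat * cos_lat ** 3 * (5 - tan_lat ** 2 + 9 * eta2)
    IIIA = nu / 720 * sin_lat * cos_lat ** 5 * (61 - 58 * tan_lat ** 2 + tan_lat ** 4)
    IV = nu * cos_lat
    V = nu / 6 * cos_lat ** 3 * (nu / rho - tan_lat ** 2)
    VI = nu / 120 * cos_lat ** 5 * (
        5 - 18 * tan_lat ** 2 + tan_lat ** 4 + 14 * eta2 - 58 * tan_lat ** 2 * eta2
    )
    dl = lon - _LON0
    north = I + II * dl ** 2 + III * dl ** 4 + IIIA * dl ** 6
    east = _E0 + IV * dl + V * dl ** 3 + VI * dl ** 5
    return east, north


def _tm_inverse(east, north):
    """Easting, northing -> OSGB36 lon/lat (radians)."""
    a, b = _AIRY_A, _AIRY_B
    e2 = 1 - (b / a) ** 2
    n = (a - b) / (a + b)

    lat = (np.asarray(north, dtype=float) - _N0) / (a * _F0) + _LAT0
    M = np.zeros_like(lat)
    for _ in range(20):
        dlat, slat = lat - _LAT0, lat + _LAT0
        M = b * _F0 * (
            (1 + n + 1.25 * n ** 2 + 1.25 * n ** 3) * dlat
            - (3 * n + 3 * n ** 2 + 2.625 * n ** 3) * np.sin(dlat) * np.cos(slat)
            + (1.875 * n ** 2 + 1.875 * n ** 3) * np.sin(2 * dlat) * np.cos(2 * slat)
            - (35 / 24) * n ** 3 * np.sin(3 * dlat) * np.cos(3 * slat)
        )
        delta = (north - _N0 - M) / (a * _F0)
        lat = lat + delta
        if np.max(np.abs(delta)) < 1e-14:
            break

    sin_lat, cos_lat, tan_lat = np.sin(lat), np.cos(lat), np.tan(lat)
    nu = a * _F0 / np.sqrt(1 - e2 * sin_lat ** 2)
    rho = a * _F0 * (1 - e2) * (1 - e2 * sin_lat ** 2) ** -1.5
    eta2 = nu / rho - 1
    sec_lat = 1.0 / cos_lat

    VII = tan_lat / (2 * rho * nu)
    VIII = tan_lat / (24 * rho * nu ** 3) * (
        5 + 3 * tan_lat ** 2 + eta2 - 9 * tan_lat ** 2 * eta2
    )
    IX = tan_lat / (720 * rho * nu ** 5) * (61 + 90 * tan_lat ** 2 + 45 * tan_lat ** 4)
    X = sec_lat / nu
    XI = sec_lat / (6 * nu ** 3) * (nu / rho + 2 * tan_lat ** 2)
    XII = sec_lat / (120 * nu ** 5) * (5 + 28 * tan_lat ** 2 + 24 * tan_lat ** 4)
    XIIA = sec_lat / (5040 * nu ** 7) * (
        61 + 662 * tan_lat ** 2 + 1320 * tan_lat ** 4 + 720 * tan_lat ** 6
    )
    de = east - _E0
    lat_out = lat - VII * de ** 2 + VIII * de ** 4 - IX * de ** 6
    lon_out = _LON0 + X * de - XI * de ** 3 + XII * de ** 5 - XIIA * de ** 7
    return lon_out, lat_out


class BritishNationalGrid:
    """WGS84 lon/lat <-> OSGB36 National Grid easting/northing in metres."""

    name = "bng"

    def to_planar(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        x, y, z = _geodetic_to_cartesian(lon, lat, _WGS_A, _WGS_B)
        x, y, z = _helmert(x, y, z, _HELMERT)
        lon36, lat36 = _cartesian_to_geodetic(x, y, z, _AIRY_A, _AIRY_B)
        return _tm_forward(lon36, lat36)

    def to_lonlat(self, x, y):
        lon36, lat36 = _tm_inverse(np.asarray(x, dtype=float),
                                   np.asarray(y, dtype=float))
        cx, cy, cz = _geodetic_to_cartesian(lon36, lat36, _AIRY_A, _AIRY_B)
        cx, cy, cz = _helmert(cx, cy, cz, _HELMERT, inverse=True)
        lon, lat = _cartesian_to_geodetic(cx, cy, cz, _WGS_A, _WGS_B)
        return np.degrees(lon), np.degrees(lat)


class LocalEquirectangular:
    """Tangent-plane projection about (lon0, lat0); exact round-trip."""

    name = "local"
    _R = 6371000.0

    def __init__(self, lon0: float = 0.0, lat0: float = 0.0):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)

    def to_planar(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = np.radians(lon - self.lon0) * self._R * np.cos(np.radians(self.lat0))
        y = np.radians(lat - self.lat0) * self._R
        return x, y

    def to_lonlat(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon0 + np.degrees(x / (self._R * np.cos(np.radians(self.lat0))))
        lat = self.lat0 + np.degrees(y / self._R)
        return lon, lat


def get_crs(name: str, **kwargs):
    """Look up a CRS by config name ('bng' or 'local')."""
    if name == "bng":
        return BritishNationalGrid()
    if name == "local":
        return LocalEquirectangular(**kwargs)
    raise ValueError(f"unknown CRS {name!r}; expected 'bng' or 'local'")
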