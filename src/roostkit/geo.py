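"""Planar projection, solar twilight and study-area geometry.

Telemetry interchange files carry WGS84 longitude/latitude; all distance
computations in the pipeline run on planar metres.  A local transverse
Mercator projection (ellipsoidal series, WGS84) provides the forward and
inverse mapping; within a few degrees of the central meridian the series is
accurate to well under a millimetre, far below GPS error.

Night assignment needs civil twilight (sun 6 degrees below the horizon).
Dawn/dusk times are computed from the standard low-precision solar
ephemeris (mean longitude, equation of centre, obliquity and equation of
time), which is accurate to about a minute -- ample for hourly duty-cycled
tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np
from shapely.geometry import Polygon, shape, mapping

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)

#: fixed-offset local clock used for duty windows and night dates (CET).
CET = timezone(timedelta(hours=1))

#: solar elevation (degrees) defining civil twilight.
CIVIL_TWILIGHT_ELEVATION = -6.0


class ProjectionError(ValueError):
    """Coordinates outside the validity region of the projection."""


def _meridian_arc(phi: np.ndarray) -> np.ndarray:
    e2, e4, e6 = _E2, _E2**2, _E2**3
    return _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
        - (35 * e6 / 3072) * np.sin(6 * phi)
    )


@dataclass(frozen=True)
class TransverseMercator:
    """Local transverse Mercator projection on the WGS84 ellipsoid.

    Parameters
    ----------
    lon0, lat0 : float
        Central meridian and latitude of origin, degrees.  The origin maps
        to planar ``(false_easting, false_northing)``.
    k0 : float
        Scale factor on the central meridian.
    max_lon_offset : float
        Validity half-width in degrees of longitude; input farther from the
        central meridian raises :class:`ProjectionError`.
    """

    lon0: float
    lat0: float
    k0: float = 1.0
    false_easting: float = 0.0
    false_northing: float = 0.0
    max_lon_offset: float = 6.0

    @property
    def spec(self) -> str:
        return (
            f"+proj=tmerc +lat_0={self.lat0} +lon_0={self.lon0} "
            f"+k={self.k0} +x_0={self.false_easting} +y_0={self.false_northing} "
            f"+ellps=WGS84 +units=m"
        )

    def forward(self, lon, lat):
        """WGS84 degrees -> planar metres (x east, y north)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 89.9):
            raise ProjectionError("latitude out of range for transverse Mercator")
        dlon = (lon - self.lon0 + 180.0) % 360.0 - 180.0
        if np.any(np.abs(dlon) > self.max_lon_offset):
            raise ProjectionError(
                f"longitude farther than {self.max_lon_offset} deg from "
                f"central meridian {self.lon0}"
            )
        phi = np.radians(lat)
        lam = np.radians(dlon)
        sin_phi, cos_phi = np.sin(phi), np.cos(phi)
        n = _A / np.sqrt(1 - _E2 * sin_phi**2)
        t = np.tan(phi) ** 2
        c = _EP2 * cos_phi**2
        a = lam * cos_phi
        m = _meridian_arc(phi)
        m0 = _meridian_arc(np.radians(self.lat0))
        x = self.k0 * n * (
            a
            + (1 - t + c) * a**3 / 6
            + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a**5 / 120
        )
        y = self.k0 * (
            m
            - m0
            + n * np.tan(phi) * (
                a**2 / 2
                + (5 - t + 9 * c + 4 * c**2) * a**4 / 24
                + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a**6 / 720
            )
        )
        return x + self.false_easting, y + self.false_northing

    def inverse(self, x, y):
        """Planar metres -> WGS84 degrees (lon, lat)."""
        x = np.asarray(x, dtype=float) - self.false_easting
        y = np.asarray(y, dtype=float) - self.false_northing
        m0 = _meridian_arc(np.radians(self.lat0))
        m = m0 + y / self.k0
        mu = m / (_A * (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256))
        e1 = (1 - np.sqrt(1 - _E2)) / (1 + np.sqrt(1 - _E2))
        phi1 = (
            mu
            + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
            + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
            + (151 * e1**3 / 96) * np.sin(6 * mu)
            + (1097 * e1**4 / 512) * np.sin(8 * mu)
        )
        sin1, cos1 = np.sin(phi1), np.cos(phi1)
        c1 = _EP2 * cos1**2
        t1 = np.tan(phi1) ** 2
        n1 = _A / np.sqrt(1 - _E2 * sin1**2)
        r1 = _A * (1 - _E2) / (1 - _E2 * sin1**2) ** 1.5
        d = x / (n1 * self.k0)
        phi = phi1 - (n1 * np.tan(phi1) / r1) * (
            d**2 / 2
            - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
            + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2)
            * d**6
            / 720
        )
        lam = (
            d
            - (1 + 2 * t1 + c1) * d**3 / 6
            + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2)
            * d**5
            / 120
        ) / cos1
        return self.lon0 + np.degrees(lam), np.degrees(phi)


# ---------------------------------------------------------------------------
# Solar position and civil twilight
# ---------------------------------------------------------------------------

def _solar_coefficients(jc):
    """Declination (rad) and equation of time (minutes) at Julian century jc."""
    jc = np.asarray(jc, dtype=float)
    l0 = np.remainder(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = np.radians(m)
    eq_centre = (
        np.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * mr) * 0.000289
    )
    true_long = l0 + eq_centre
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(eps) * np.sin(np.radians(app_long)))
    y = np.tan(eps / 2) ** 2
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2 * ecc * np.sin(mr)
        + 4 * ecc * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y**2 * np.sin(4 * l0r)
        - 1.25 * ecc**2 * np.sin(2 * mr)
    )
    return decl, eot


def _julian_century(times_utc) -> np.ndarray:
    ts = np.asarray(times_utc, dtype="datetime64[s]").astype("int64")
    jd = ts / 86400.0 + 2440587.5
    return (jd - 2451545.0) / 36525.0


def solar_elevation(times_utc, lon, lat) -> np.ndarray:
    """Solar elevation angle in degrees (no refraction) at UTC instants."""
    jc = _julian_century(times_utc)
    decl, eot = _solar_coefficients(jc)
    ts = np.asarray(times_utc, dtype="datetime64[s]").astype("int64")
    minutes_utc = (ts % 86400) / 60.0
    tst = np.remainder(minutes_utc + eot + 4.0 * np.asarray(lon, dtype=float), 1440.0)
    hour_angle = np.radians(tst / 4.0 - 180.0)
    phi = np.radians(np.asarray(lat, dtype=float))
    sin_el = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(hour_angle)
    return np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def twilight_times(night: date, lon, lat, elevation: float = CIVIL_TWILIGHT_ELEVATION):
    """UTC dawn and dusk (sun crossing `elevation`) for a calendar date.

    Vectorised over lon/lat.  Returns ``(dawn_utc, dusk_utc)`` as numpy
    datetime64[s] arrays (scalars for scalar input).  Polar day/night never
    occurs at the latitudes this pipeline targets; a crossing that does not
    exist raises ValueError.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    noon_guess = np.datetime64(datetime(night.year, night.month, night.day, 12), "s")
    jc = _julian_century(noon_guess)
    decl, eot = _solar_coefficients(jc)
    cos_h = (
        np.cos(np.radians(90.0 - elevation))
        - np.sin(np.radians(lat)) * np.sin(decl)
    ) / (np.cos(np.radians(lat)) * np.cos(decl))
    if np.any(np.abs(cos_h) > 1.0):
        raise ValueError("sun never crosses the twilight elevation on this date")
    ha_minutes = 4.0 * np.degrees(np.arccos(cos_h))
    solar_noon = 720.0 - 4.0 * lon - eot  # minutes after UTC midnight
    midnight = np.datetime64(datetime(night.year, night.month, night.day), "s")
    dawn = midnight + ((solar_noon - ha_minutes) * 60).astype("timedelta64[s]")
    dusk = midnight + ((solar_noon + ha_minutes) * 60).astype("timedelta64[s]")
    return dawn, dusk


# ---------------------------------------------------------------------------
# Study-area polygons
# ---------------------------------------------------------------------------

def read_study_area(path) -> Polygon:
    """Read a GeoJSON Polygon (WGS84) from `path`."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    poly = shape(geom)
    if poly.is_empty or not poly.is_valid:
        raise ValueError(f"degenerate study-area polygon in {path}")
    return poly

def write_study_area(path, polygon: Polygon) -> None:
    with open(path, "w") as fh:
        json.dump(mapping(polygon), fh)

def polygon_to_planar(polygon: Polygon, projection: TransverseMercator) -> Polygon:
    lon, lat = np.asarray(polygon.exterior.coords).T
    x, y = projection.forward(lon, lat)
    return Polygon(np.column_stack([x, y]))

def polygon_to_lonlat(polygon: Polygon, projection: TransverseMercator) -> Polygon:
    x, y = np.asarray(polygon.exterior.coords).T
    lon, lat = projection.inverse(x, y)
    return Polygon(np.column_stack([lon, lat]))
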