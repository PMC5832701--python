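"""Spherical great-circle geometry on the mean-radius Earth sphere.

All functions take and return coordinates in decimal degrees
(longitude in (-180, 180], latitude in [-90, 90]) and distances in
kilometres, using the IUGG mean Earth radius of 6371.0088 km.  Bearings
are degrees clockwise from north in [0, 360).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

EARTH_RADIUS_KM = 6371.0088


def _check_coords(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise InvalidInputError("non-finite coordinate")
    if np.any(np.abs(lon) > 360.0) or np.any(np.abs(lat) > 90.0):
        raise InvalidInputError(
            f"coordinate out of range: lon={lon}, lat={lat}"
        )


def great_circle_distance(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle (haversine) distance in km between two points.

    Accepts scalars or broadcastable arrays.
    """
    _check_coords(lon1, lat1)
    _check_coords(lon2, lat2)
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def initial_bearing(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    _check_coords(lon1, lat1)
    _check_coords(lon2, lat2)
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    if np.ndim(theta) == 0:
        return float(theta)
    return theta


def destination_point(lon, lat, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along a great circle
    starting at the given initial bearing.  Returns (lon, lat) degrees."""
    _check_coords(lon, lat)
    phi1 = np.radians(np.asarray(lat, dtype=float))
    lam1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta)
                     + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lam2 = lam1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    lat2 = np.degrees(phi2)
    if np.ndim(lon2) == 0:
        return float(lon2), float(lat2)
    return lon2, lat2


def gc_latitude_at_longitude(lon1, lat1, lon2, lat2, lon) -> np.ndarray | float:
    """Latitude at which the great circle through two points crosses ``lon``.

    Uses the standard intermediate-point formula
    tan(phi) = (tan(phi1) sin(lam2-lam) + tan(phi2) sin(lam-lam1)) / sin(lam2-lam1).
    Returns NaN where the two endpoint longitudes coincide (the great
    circle is a meridian and its longitude crossing is degenerate).
    """
    _check_coords(lon1, lat1)
    _check_coords(lon2, lat2)
    lam1, phi1, lam2, phi2, lam = (np.radians(np.asarray(x, dtype=float))
                                   for x in (lon1, lat1, lon2, lat2, lon))
    denom = np.sin(lam2 - lam1)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (np.tan(phi1) * np.sin(lam2 - lam)
               + np.tan(phi2) * np.sin(lam - lam1))
        phi = np.arctan(num / denom)
    phi = np.where(np.abs(denom) < 1e-12, np.nan, phi)
    out = np.degrees(phi)
    if np.ndim(out) == 0:
        return float(out)
    return out
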