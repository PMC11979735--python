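"""Spherical geometry, calendar and solar helpers shared across the pipeline.

All great-circle distances are haversine distances on a sphere of radius
6371.0088 km (the IUGG mean Earth radius). The error relative to a full
geodesic on the WGS84 ellipsoid is below 0.5% at the scales involved here
(hundreds to thousands of km), which is negligible next to daily-position
averaging error.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: metres per degree of latitude on the reference sphere (used for the
#: nest-detection stationarity rule).
M_PER_DEG_LAT = 111_320.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    lat1, lon1, lat2, lon2 = (
        np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2)
    )
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def _to_unit(lat_deg: float, lon_deg: float) -> np.ndarray:
    lat = math.radians(lat_deg)
    lon = math.radians(lon_deg)
    return np.array(
        [math.cos(lat) * math.cos(lon), math.cos(lat) * math.sin(lon), math.sin(lat)]
    )


def _from_unit(v: np.ndarray) -> tuple[float, float]:
    v = v / np.linalg.norm(v)
    lat = math.degrees(math.asin(np.clip(v[2], -1.0, 1.0)))
    lon = math.degrees(math.atan2(v[1], v[0]))
    return lat, lon


def gc_waypoint(lat1: float, lon1: float, lat2: float, lon2: float, frac: float):
    """Point a fraction ``frac`` of the way along the great circle 1 -> 2.

    Spherical linear interpolation; ``frac`` outside [0, 1] extrapolates.
    """
    a = _to_unit(lat1, lon1)
    b = _to_unit(lat2, lon2)
    omega = math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0)))
    if omega < 1e-12:
        return lat1, lon1
    v = (math.sin((1.0 - frac) * omega) * a + math.sin(frac * omega) * b) / math.sin(omega)
    return _from_unit(v)


def circular_mean_deg(angles_deg) -> float:
    """Vector mean of angles in degrees, in (-180, 180] — antimeridian safe."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.nanmean(np.sin(a)), np.nanmean(np.cos(a))
    return math.degrees(math.atan2(s, c))


# --- calendar -------------------------------------------------------------

def date_to_doy(d: dt.date) -> int:
    return d.timetuple().tm_yday


def doy_to_date(year: int, doy: float) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=int(round(doy)) - 1)


def march_equinox_doy(year: int) -> int:
    """Day-of-year of the astronomical March equinox (approximation).

    Valid to within a day for 1980-2100, which is ample for a +/-(14, 18) day
    masking window.
    """
    day = 20.8431 + 0.242194 * (year - 1980) - (year - 1980) // 4
    return date_to_doy(dt.date(year, 3, int(day)))


# --- solar geometry -------------------------------------------------------

def solar_declination_deg(doy) -> np.ndarray | float:
    """Approximate solar declination (degrees) for a given day of year."""
    doy = np.asarray(doy, dtype=float)
    d = 23.44 * np.sin(2.0 * np.pi * (doy + 284.0) / 365.0)
    return float(d) if np.ndim(d) == 0 else d


def min_solar_elevation_deg(lat_deg, doy):
    """Solar elevation at local solar midnight (degrees, northern hemisphere).

    At midnight the sun sits ``lat + declination - 90`` degrees above the
    horizon; values above the chosen twilight threshold mean no dark night
    (polar day for light-level geolocation purposes).
    """
    return np.asarray(lat_deg, dtype=float) + solar_declination_deg(doy) - 90.0


def has_dark_night(lat_deg, doy, twilight_deg: float = -6.0):
    """True when the night gets darker than civil twilight (default -6 deg)."""
    out = min_solar_elevation_deg(lat_deg, doy) < twilight_deg
    return bool(out) if np.ndim(out) == 0 else out
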