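"""Reading, validation and preprocessing of tracking data.

Tracks travel as flat tables (one row per fix) with columns
``individual_id, timestamp, lat, lon, device``. Preprocessing applies the
study's ingestion rules: a 120 km/h implied-speed filter for GPS fixes,
equinox latitude masking for geolocators, daily averaging (circular in
longitude) and a winter-to-arrival coverage check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

from .geo import circular_mean_deg, haversine_km, march_equinox_doy

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual_id", "timestamp", "lat", "lon", "device")

SPEED_LIMIT_KMH = 120.0
EQUINOX_DAYS_BEFORE = 14
EQUINOX_DAYS_AFTER = 18


class TrackReadError(ValueError):
    pass


def read_tracks(path, device: str | None = None) -> pd.DataFrame:
    """Read a track CSV, validate, sort and de-duplicate.

    Rows are sorted per individual by timestamp; duplicate
    (individual, timestamp) pairs keep the first occurrence (logged).
    ``device`` optionally restricts to one device type.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackReadError(f"missing required column(s): {', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise TrackReadError(f"unparseable timestamp at data row {bad}")
    df = df.assign(timestamp=ts)
    out_of_range = ~df["lat"].between(-90, 90) & df["lat"].notna()
    if "lat_missing" not in df.columns:
        df["lat_missing"] = df["lat"].isna()
    df.loc[out_of_range, ["lat"]] = np.nan
    df.loc[out_of_range, "lat_missing"] = True
    if (~df["lon"].between(-180, 180) & df["lon"].notna()).any():
        raise TrackReadError("longitude out of [-180, 180]")
    if device is not None:
        df = df[df["device"] == device]
    n0 = len(df)
    df = df.sort_values(["individual_id", "timestamp"], kind="mergesort")
    df = df.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    if len(df) < n0:
        logger.warning("dropped %d duplicate-timestamp fixes", n0 - len(df))
    return df.reset_index(drop=True)


def write_tracks(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    cols = [c for c in REQUIRED_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


def filter_speed_outliers(
    fixes: pd.DataFrame, max_speed_kmh: float = SPEED_LIMIT_KMH, drop: str = "earlier"
) -> pd.DataFrame:
    """Iteratively remove fixes implying travel faster than ``max_speed_kmh``.

    A fix bounded by two violating pairs (implausible speed both into and out
    of it) is a teleporting spike and is removed outright. For an isolated
    violating pair the ``earlier`` fix is removed (configurable to
    ``"later"``). The scan repeats until no violation remains, so the output
    is a fixpoint. Removal counts are logged. Fixes with missing latitude
    are passed through untouched.
    """
    if drop not in ("earlier", "later"):
        raise ValueError("drop must be 'earlier' or 'later'")
    located = fixes["lat"].notna()
    keep_parts = [fixes[~located]]
    removed = 0
    for _, grp in fixes[located].groupby("individual_id", sort=False):
        g = grp.sort_values("timestamp")
        while len(g) > 1:
            lat = g["lat"].to_numpy()
            lon = g["lon"].to_numpy()
            t = g["timestamp"].to_numpy()
            dt_h = np.diff(t).astype("timedelta64[s]").astype(float) / 3600.0
            dist = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
            with np.errstate(divide="ignore", invalid="ignore"):
                speed = np.where(dt_h > 0, dist / dt_h, np.inf * (dist > 0))
            viol = speed > max_speed_kmh
            if not viol.any():
                break
            # spikes: fixes violating on both sides
            to_drop = [i for i in range(1, len(g) - 1) if viol[i - 1] and viol[i]]
            if not to_drop:
                last = -2
                for b in np.flatnonzero(viol):
                    if b == last + 1:
                        continue  # overlapping pair: re-evaluate next pass
                    to_drop.append(b if drop == "earlier" else b + 1)
                    last = b
            g = g.drop(g.index[to_drop])
            removed += len(to_drop)
        keep_parts.append(g)
    if removed:
        logger.info("speed filter removed %d fixes (> %.0f km/h)", removed, max_speed_kmh)
    out = pd.concat(keep_parts).sort_values(
        ["individual_id", "timestamp"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def mask_equinox_latitudes(
    fixes: pd.DataFrame,
    days_before: int = EQUINOX_DAYS_BEFORE,
    days_after: int = EQUINOX_DAYS_AFTER,
) -> pd.DataFrame:
    """Blank geolocator latitudes around the March equinox.

    The window is [equinox - days_before, equinox + days_after], closed on
    both ends, using the astronomical equinox of each fix's year. Longitudes
    are retained. Applying this to GPS fixes is an error — the rule exists
    because light-level latitudes are unreliable near the equinox.
    """
    if (fixes["device"] != "GLS").any():
        raise ValueError("equinox masking applies to GLS tracks only")
    out = fixes.copy()
    ts = pd.to_datetime(out["timestamp"], utc=True)
    doy = ts.dt.dayofyear
    eq = ts.dt.year.map(march_equinox_doy)
    in_window = (doy >= eq - days_before) & (doy <= eq + days_after)
    out.loc[in_window, "lat"] = np.nan
    if "lat_missing" in out.columns:
        out.loc[in_window, "lat_missing"] = True
    else:
        out["lat_missing"] = out["lat"].isna()
    return out


def daily_average(fixes: pd.DataFrame) -> pd.DataFrame:
    """Collapse fixes to one position per individual per UTC calendar day.

    Latitude is the arithmetic mean of the day's located fixes (NaN when all
    are missing); longitude is a circular (vector) mean so tracks crossing
    the antimeridian average correctly.
    """
    df = fixes.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    df["date"] = ts.dt.date
    df["year"] = ts.dt.year
    df["doy"] = ts.dt.dayofyear
    lon_rad = np.radians(df["lon"].to_numpy(dtype=float))
    df["_sin"] = np.sin(lon_rad)
    df["_cos"] = np.cos(lon_rad)
    keys = ["individual_id", "year", "doy", "date"]
    grouped = df.groupby(keys, sort=True).agg(
        lat=("lat", "mean"), _sin=("_sin", "mean"), _cos=("_cos", "mean")
    )
    grouped["lon"] = np.degrees(np.arctan2(grouped["_sin"], grouped["_cos"]))
    grouped = grouped.drop(columns=["_sin", "_cos"]).reset_index()
    if "device" in fixes.columns:
        dev = df.groupby(["individual_id"])["device"].first()
        grouped = grouped.join(dev, on="individual_id")
    return grouped


@dataclass
class CoverageReport:
    individual_id: str
    year: int
    passed: bool
    missing_days: list[int] = field(default_factory=list)


def check_coverage(daily: pd.DataFrame, arrival_doy: float) -> CoverageReport:
    """Check for at least one position per day from 1 January to arrival.

    ``daily`` must contain a single individual-year. Days after arrival are
    not required (the inclusion rule ends at arrival at the Arctic Circle).
    """
    ids = daily["individual_id"].unique()
    years = daily["year"].unique()
    if len(ids) != 1 or len(years) != 1:
        raise ValueError("check_coverage expects a single individual-year")
    have = set(daily["doy"].astype(int))
    needed = range(1, int(np.floor(arrival_doy)) + 1)
    missing = [d for d in needed if d not in have]
    return CoverageReport(str(ids[0]), int(years[0]), not missing, missing)


# --- study-site polygons ----------------------------------------------------

def read_site_polygons(path) -> dict:
    """Read study-site polygons from GeoJSON (WGS84, lon/lat order).

    Returns a mapping site_id -> shapely geometry. Accepts a Feature,
    FeatureCollection or bare geometry with a ``site_id`` property.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = {}
    for f in feats:
        geom = shape(f["geometry"] if "geometry" in f else f)
        site = f.get("properties", {}).get("site_id", f"site_{len(out)}")
        out[site] = geom
    return out


def point_in_site(lat: float, lon: float, polygon) -> bool:
    return polygon.contains(Point(lon, lat))
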