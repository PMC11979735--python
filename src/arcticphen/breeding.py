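"""Egg-laying date detection from GPS stationarity, geolocator darkness
bouts, and field back-calculation, plus the cross-method validation.

The central GPS rule (used for geese): a nest is a run of at least three
consecutive days on which the daily standard deviation of latitude falls
below 25.4 m, and the laying date is the first day of that run. Degrees are
converted to metres with 111,320 m per degree of latitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo import M_PER_DEG_LAT, circular_mean_deg, haversine_km

NEST_SD_THRESHOLD_M = 25.4
NEST_MIN_DAYS = 3
BUZZARD_RADIUS_M = 3.0
BUZZARD_MIN_HOURS = 24.0
DARKNESS_MIN_BOUT_MIN = 60.0


@dataclass
class NestRecord:
    individual_id: str
    year: int
    laying_doy: float
    nest_lat: float
    nest_lon: float
    method: str


def detect_nest_goose(
    fixes: pd.DataFrame,
    sd_threshold_m: float = NEST_SD_THRESHOLD_M,
    min_days: int = NEST_MIN_DAYS,
    after_doy: float | None = None,
) -> NestRecord | None:
    """Stationarity-based nest detection for incubating geese.

    Works on raw fixes (not daily means): for each day the standard
    deviation of latitude is computed and converted to metres; the first run
    of at least ``min_days`` consecutive days below ``sd_threshold_m`` marks
    a nest, with the laying date the first day of the run and the nest
    position the mean position over the run. Days with fewer than two fixes
    carry no spread information and cannot qualify. Returns None when no
    qualifying run exists.
    """
    df = fixes.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    df["doy"] = ts.dt.dayofyear
    df["_year"] = ts.dt.year
    if after_doy is not None:
        df = df[df["doy"] >= after_doy]
    if df.empty:
        return None
    per_day = df.groupby("doy").agg(
        sd_lat=("lat", lambda x: x.std(ddof=1)), n=("lat", "size")
    )
    per_day["quiet"] = (per_day["sd_lat"] * M_PER_DEG_LAT < sd_threshold_m) & (
        per_day["n"] >= 2
    )
    run_start = _first_run(per_day.index.to_numpy(), per_day["quiet"].to_numpy(), min_days)
    if run_start is None:
        return None
    run_days = range(run_start, run_start + min_days)
    run = df[df["doy"].isin(run_days)]
    return NestRecord(
        str(df["individual_id"].iloc[0]),
        int(df["_year"].iloc[0]),
        float(run_start),
        float(run["lat"].mean()),
        circular_mean_deg(run["lon"].to_numpy()),
        "gps_goose",
    )


def _first_run(days: np.ndarray, ok: np.ndarray, min_days: int) -> int | None:
    """First day starting ``min_days`` consecutive calendar days of ``ok``."""
    ok_days = days[ok]
    if len(ok_days) < min_days:
        return None
    for i in range(len(ok_days) - min_days + 1):
        if ok_days[i + min_days - 1] - ok_days[i] == min_days - 1:
            return int(ok_days[i])
    return None


def detect_nest_buzzard(
    fixes: pd.DataFrame,
    radius_m: float = BUZZARD_RADIUS_M,
    min_hours: float = BUZZARD_MIN_HOURS,
) -> NestRecord | None:
    """Nest detection for raptors: a stay of more than a day within 3 m.

    Finds the first period strictly longer than ``min_hours`` during which
    all fixes stay within ``radius_m`` of the period's first fix (a
    computationally bounded reading of "difference between GPS positions of
    less than 3 m"); the laying date is the first day of that period.
    """
    df = fixes.sort_values("timestamp").reset_index(drop=True)
    ts = pd.to_datetime(df["timestamp"], utc=True)
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    n = len(df)
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n and haversine_km(lat[i], lon[i], lat[j + 1], lon[j + 1]) * 1000.0 < radius_m:
            j += 1
        dur_h = (ts.iloc[j] - ts.iloc[i]).total_seconds() / 3600.0
        if dur_h > min_hours:
            window = df.iloc[i : j + 1]
            return NestRecord(
                str(df["individual_id"].iloc[0]),
                int(ts.iloc[i].year),
                float(ts.iloc[i].dayofyear),
                float(window["lat"].mean()),
                circular_mean_deg(window["lon"].to_numpy()),
                "gps_buzzard",
            )
    return None


def laying_from_gls_darkness(
    light_record: pd.DataFrame,
    min_bout_min: float = DARKNESS_MIN_BOUT_MIN,
    min_consecutive_days: int = 3,
) -> NestRecord | None:
    """Incubation onset from darkness bouts recorded during polar day.

    ``light_record`` needs, for one individual-year during the
    continuous-daylight period, columns ``doy``, ``max_dark_bout_min`` (the
    longest darkness bout that day, minutes, from the logger being covered on
    the nest) and boolean ``polar_day``. "Regular periods of darkness" is
    operationalised as ``min_consecutive_days`` consecutive days each with a
    bout of at least ``min_bout_min`` minutes; the laying date is the first
    such day. Raises when any row falls outside the continuous-daylight
    period (darkness bouts are only diagnostic under the midnight sun).
    """
    if not light_record["polar_day"].astype(bool).all():
        raise ValueError("light record extends outside the continuous-daylight period")
    rec = light_record.sort_values("doy")
    ok = (rec["max_dark_bout_min"] >= min_bout_min).to_numpy()
    start = _first_run(rec["doy"].to_numpy(), ok, min_consecutive_days)
    if start is None:
        return None
    ind = str(rec["individual_id"].iloc[0]) if "individual_id" in rec.columns else ""
    year = int(rec["year"].iloc[0]) if "year" in rec.columns else 0
    return NestRecord(ind, year, float(start), np.nan, np.nan, "gls_darkness")


def back_calculate_laying(
    hatch_doy: float,
    incubation_days: float,
    clutch_size: int = 1,
    laying_interval_days: float = 0.0,
) -> float:
    """Laying date from a hatch date, subtracting incubation (and optionally
    one laying interval per egg after the first)."""
    if incubation_days < 0 or laying_interval_days < 0 or clutch_size < 1:
        raise ValueError("durations must be non-negative and clutch_size >= 1")
    return hatch_doy - incubation_days - (clutch_size - 1) * laying_interval_days


@dataclass
class CorrelationReport:
    r: float
    t: float
    df: int
    p: float
    n: int


def crossvalidate_laying_methods(
    tracking_means: pd.Series | np.ndarray, field_means: pd.Series | np.ndarray
) -> CorrelationReport:
    """Pearson correlation between yearly mean laying dates from tracking vs
    field data, with the paired t statistic on n-2 degrees of freedom."""
    x = np.asarray(tracking_means, dtype=float)
    y = np.asarray(field_means, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired year-means")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    denom = max(1.0 - r**2, np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / denom)
    return CorrelationReport(float(r), float(t), n - 2, float(p), n)


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def extract_laying_dates(
    fixes: pd.DataFrame,
    arrivals: pd.DataFrame | None = None,
    population: str | None = None,
    method: str = "gps_goose",
    site_polygon=None,
    **kwargs,
) -> pd.DataFrame:
    """Detect nests for every individual-year of raw GPS fixes.

    ``arrivals`` (columns individual_id, year, arrival_doy) restricts the
    search to fixes after each bird's Arctic arrival; ``site_polygon``
    (shapely) drops nests outside the study site. Returns a tidy laying-date
    table (absences omitted).
    """
    detector = {"gps_goose": detect_nest_goose, "gps_buzzard": detect_nest_buzzard}[method]
    ts = pd.to_datetime(fixes["timestamp"], utc=True)
    df = fixes.assign(_year=ts.dt.year)
    arr_map = {}
    if arrivals is not None:
        arr_map = {
            (r.individual_id, int(r.year)): r.arrival_doy
            for r in arrivals.itertuples(index=False)
            if np.isfinite(r.arrival_doy)
        }
    rows = []
    for (ind, year), grp in df.groupby(["individual_id", "_year"], sort=True):
        kw = dict(kwargs)
        if method == "gps_goose":
            kw.setdefault("after_doy", arr_map.get((ind, int(year))))
        rec = detector(grp, **kw)
        if rec is None:
            continue
        if site_polygon is not None and np.isfinite(rec.nest_lat):
            from shapely.geometry import Point

            if not site_polygon.contains(Point(rec.nest_lon, rec.nest_lat)):
                continue
        rows.append(
            {
                "population": population,
                "individual_id": rec.individual_id,
                "year": rec.year,
                "laying_doy": rec.laying_doy,
                "nest_lat": rec.nest_lat,
                "nest_lon": rec.nest_lon,
                "method": rec.method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "population",
            "individual_id",
            "year",
            "laying_doy",
            "nest_lat",
            "nest_lon",
            "method",
        ],
    )
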