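"""Per individual-year migration phenology: departure, Arctic arrival,
migration distance and travel speed.

Departure is anchored to the mid-winter centroid (median January-February
position). GPS and geolocator tracks use different estimators because the
two device types fail differently: GPS positions are accurate year-round, so
departure is the last spring day within 200 km of the centroid and arrival
the first daily position above the Arctic Circle (66.33 N); geolocator
latitudes are noisy (and absent near the equinox and during polar day), so
departure is the onset of sustained directional movement away from the
centroid and arrival the first day after the last dark night.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_km

ARCTIC_CIRCLE_LAT = 66.33
DEPARTURE_RADIUS_KM = 200.0
SPRING_CUTOFF_DOY = 182  # 1 July (non-leap)


class PhenologyError(ValueError):
    pass


@dataclass
class WinterCentroid:
    individual_id: str
    year: int
    lat: float
    lon: float
    n_days: int


def winter_centroid(daily: pd.DataFrame, min_days: int = 10) -> WinterCentroid:
    """Median January-February position of one individual-year.

    Requires at least one located day in each of January and February and at
    least ``min_days`` located days overall; medians are taken independently
    per coordinate.
    """
    ids = daily["individual_id"].unique()
    years = daily["year"].unique()
    if len(ids) != 1 or len(years) != 1:
        raise PhenologyError("winter_centroid expects a single individual-year")
    feb_end = 60 if _is_leap(int(years[0])) else 59
    win = daily[(daily["doy"] <= feb_end) & daily["lat"].notna()]
    jan = win[win["doy"] <= 31]
    feb = win[win["doy"] > 31]
    if len(jan) == 0 or len(feb) == 0 or len(win) < min_days:
        raise PhenologyError(
            f"{ids[0]} {years[0]}: insufficient Jan-Feb coverage "
            f"({len(win)} days, need >= {min_days} with both months present)"
        )
    return WinterCentroid(
        str(ids[0]),
        int(years[0]),
        float(win["lat"].median()),
        float(win["lon"].median()),
        len(win),
    )


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def departure_date_gps(
    daily: pd.DataFrame,
    centroid: WinterCentroid,
    radius_km: float = DEPARTURE_RADIUS_KM,
    spring_cutoff_doy: int = SPRING_CUTOFF_DOY,
) -> float | None:
    """Last spring day within ``radius_km`` of the mid-winter centroid.

    Implemented as the latest located day at or before the cutoff (default
    1 July) that lies inside the radius, provided the track actually leaves
    the radius afterwards; brief excursions beyond the radius followed by a
    return therefore postpone departure. Returns None when the bird never
    leaves (excluded downstream).
    """
    d = daily[daily["lat"].notna() & (daily["doy"] <= spring_cutoff_doy)]
    if d.empty:
        return None
    dist = haversine_km(d["lat"].to_numpy(), d["lon"].to_numpy(), centroid.lat, centroid.lon)
    inside = d["doy"].to_numpy()[dist <= radius_km]
    if len(inside) == 0:
        return None
    last_inside = float(inside.max())
    after = d["doy"].to_numpy() > last_inside
    if not after.any():
        return None  # never observed outside the radius before the cutoff
    return last_inside


def departure_date_gls(
    daily: pd.DataFrame,
    centroid: WinterCentroid,
    k: int = 3,
    d_min_km: float = 300.0,
) -> float | None:
    """Onset of sustained directional movement away from the centroid.

    First located day opening a run of ``k`` consecutive located days that
    all lie at least ``d_min_km`` from the mid-winter centroid (and whose
    preceding located day, if any, lay closer). Requiring several days
    beyond the displacement floor makes the rule robust both to geolocator
    position noise (a lone spike never qualifies) and to stopover dwell
    (which stalls, but does not reverse, the displacement) — a deterministic
    surrogate for the visual inspection used with raw geolocator tracks.

    Days whose latitude was blanked in the equinox window still contribute
    through their (retained, reliable) longitude: the displacement proxy for
    such days is the east-west great-circle distance at the centroid's
    latitude, which underestimates true displacement and therefore never
    triggers departure spuriously.
    """
    d = daily[daily["lon"].notna()].sort_values("doy")
    if len(d) < k:
        return None
    doy = d["doy"].to_numpy(dtype=float)
    lat = d["lat"].to_numpy(dtype=float)
    lon = d["lon"].to_numpy(dtype=float)
    dist = haversine_km(np.where(np.isnan(lat), centroid.lat, lat), lon, centroid.lat, centroid.lon)
    away = dist >= d_min_km
    for i in range(len(doy) - k + 1):
        if not away[i : i + k].all():
            continue
        if i > 0 and away[i - 1]:
            continue  # not the onset
        return float(doy[i])
    return None


def arrival_date_gps(daily: pd.DataFrame, arctic_lat: float = ARCTIC_CIRCLE_LAT) -> float | None:
    """First day with daily latitude above the Arctic Circle."""
    d = daily[daily["lat"].notna() & (daily["lat"] > arctic_lat)]
    if d.empty:
        return None
    return float(d["doy"].min())


def arrival_date_gls(
    light_record: pd.DataFrame, spring_cutoff_doy: int = SPRING_CUTOFF_DOY
) -> float:
    """First day after the last dark night (geolocator Arctic arrival proxy).

    ``light_record`` needs columns ``doy`` and boolean ``dark_night`` for one
    individual-year; days after the cutoff are ignored. Raises if the spring
    record contains no dark night at all (malformed input).
    """
    rec = light_record[light_record["doy"] <= spring_cutoff_doy]
    dark = rec[rec["dark_night"].astype(bool)]
    if dark.empty:
        raise PhenologyError("light record has no dark nights before the cutoff")
    return float(dark["doy"].max()) + 1.0


def migration_distance(
    daily: pd.DataFrame,
    departure_doy: float,
    arrival_doy: float,
    gap_flag_days: int = 3,
) -> tuple[float, bool]:
    """Cumulative great-circle distance over daily positions in [Dd, Da].

    Missing days inside the window are bridged by summing over the available
    consecutive positions (equivalent to linear interpolation of the path);
    returns ``(distance_km, gap_flag)`` where the flag marks any bridged gap
    longer than ``gap_flag_days`` days.
    """
    if arrival_doy <= departure_doy:
        raise PhenologyError("arrival must postdate departure")
    d = daily[
        daily["lat"].notna()
        & (daily["doy"] >= departure_doy)
        & (daily["doy"] <= arrival_doy)
    ].sort_values("doy")
    if len(d) < 2:
        return 0.0, True
    lat = d["lat"].to_numpy()
    lon = d["lon"].to_numpy()
    dist = float(np.sum(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))
    gaps = np.diff(d["doy"].to_numpy())
    return dist, bool((gaps > gap_flag_days).any())


def travel_speed(migration_km: float, departure_doy: float, arrival_doy: float) -> float:
    """Total migration distance / days between departure and Arctic arrival."""
    dt = arrival_doy - departure_doy
    if dt <= 0:
        raise PhenologyError("arrival must postdate departure")
    return migration_km / dt


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def extract_migration_phenology(
    daily: pd.DataFrame,
    population: str | None = None,
    light_record: pd.DataFrame | None = None,
    radius_km: float = DEPARTURE_RADIUS_KM,
    arctic_lat: float = ARCTIC_CIRCLE_LAT,
    spring_cutoff_doy: int = SPRING_CUTOFF_DOY,
    gls_k: int = 3,
    gls_d_min_km: float = 300.0,
    min_winter_days: int = 10,
) -> pd.DataFrame:
    """Extract Dd, Da, MD and V for every individual-year in ``daily``.

    Individual-years that fail the winter-coverage requirement or yield no
    departure/arrival are reported with NaN dates and a reason flag rather
    than dropped silently.
    """
    rows = []
    for (ind, year), grp in daily.groupby(["individual_id", "year"], sort=True):
        device = grp["device"].iloc[0] if "device" in grp.columns else "GPS"
        rec = {
            "population": population,
            "individual_id": ind,
            "year": int(year),
            "device": device,
            "departure_doy": np.nan,
            "arrival_doy": np.nan,
            "migration_km": np.nan,
            "travel_speed_km_day": np.nan,
            "flag": "",
        }
        try:
            cen = winter_centroid(grp, min_days=min_winter_days)
        except PhenologyError as err:
            rec["flag"] = f"no_winter_centroid: {err}"
            rows.append(rec)
            continue
        if device == "GLS":
            dd = departure_date_gls(grp, cen, k=gls_k, d_min_km=gls_d_min_km)
            if light_record is None:
                rec["flag"] = "no_light_record"
                rows.append(rec)
                continue
            lr = light_record[
                (light_record["individual_id"] == ind) & (light_record["year"] == year)
            ]
            try:
                da = arrival_date_gls(lr, spring_cutoff_doy)
            except PhenologyError:
                da = None
        else:
            dd = departure_date_gps(grp, cen, radius_km, spring_cutoff_doy)
            da = arrival_date_gps(grp, arctic_lat)
        if dd is None or da is None:
            rec["flag"] = "no_departure" if dd is None else "no_arrival"
            rows.append(rec)
            continue
        if da <= dd:
            rec["flag"] = "arrival_before_departure"
            rows.append(rec)
            continue
        md, gappy = migration_distance(grp, dd, da)
        rec.update(
            departure_doy=dd,
            arrival_doy=da,
            migration_km=md,
            travel_speed_km_day=travel_speed(md, dd, da),
            flag="gappy_track" if gappy else "",
        )
        rows.append(rec)
    return pd.DataFrame(rows)
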