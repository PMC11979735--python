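"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study system end to end: daily-resolution GPS
tracks with winter residency, stopover-structured northward migration, Arctic
residency and a nesting phase; geolocator-style degradation (positional
noise, equinox latitude loss, truncation at the onset of polar day); annual
snow-cover decline series with cloud gaps; and population-level couplings
between event dates, snowmelt and calendar year with stated noise levels.

Event dates are generated first on a continuous day-of-year scale from an
explicit linear mixed model, then rounded to whole days to schedule track
fixes, so downstream extraction can be checked against exact ground truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import (
    gc_waypoint,
    haversine_km,
    has_dark_night,
    march_equinox_doy,
    doy_to_date,
)

ARCTIC_CIRCLE_LAT = 66.33


class GenerationError(ValueError):
    """Raised when a scenario implies an infeasible individual-year."""


@dataclass
class PopulationScenario:
    """Generative description of one tracked population.

    Event-date couplings
    --------------------
    Arrival for individual *i* in year *y* is drawn as::

        Da = mean_arrival + b_as * (Dsm_y - snowmelt_mean_doy)
                          + b_ay * (y - mean(years)) + u_i + e_iy

    with ``u_i ~ N(0, sd_individual)`` and ``e_iy ~ N(0, sd_residual)``.
    Because the snowmelt date itself carries the trend ``snowmelt_trend``,
    the marginal arrival-over-time trend (the estimand of a regression of
    arrival on year) is ``beta_arrival_year + beta_arrival_snowmelt *
    snowmelt_trend`` — exposed as :attr:`marginal_arrival_trend`.

    Laying is coupled to both snowmelt and the individual's own arrival::

        Dl = mean_laying + b_ls * (Dsm_y - snowmelt_mean_doy)
                         + b_la * (Da - mean_arrival) + e'_iy
    """

    population_id: str = "pop1"
    n_individuals: int = 30
    years: tuple[int, ...] = tuple(range(2009, 2024))
    winter_centroid: tuple[float, float] = (52.3, 5.2)   # (lat, lon), NL coast
    breeding_site: tuple[float, float] = (69.0, 49.0)    # Kolguev-like
    n_stopovers: int = 3
    mean_departure_doy: float = 100.0
    mean_travel_days: float = 40.0
    snowmelt_mean_doy: float = 160.0
    snowmelt_trend: float = -1.0           # days / year
    snowmelt_sd: float = 8.0               # interannual anomaly SD, days
    beta_arrival_snowmelt: float = 0.5     # days / day of snowmelt
    beta_laying_snowmelt: float = 0.22
    beta_laying_arrival: float = 0.20
    beta_arrival_year: float = 0.0         # direct year effect, days / year
    departure_tracks_arrival: bool = True
    prelaying_days: float = 10.0
    sd_individual: float = 2.0             # random-intercept SD, days
    sd_residual: float = 3.0               # residual SD, days
    sd_travel_days: float = 2.0
    device: str = "GPS"
    seed: int = 0

    # track texture (see docs/methods.md)
    winter_jitter_km: float = 5.0
    prenest_jitter_m: float = 200.0
    nest_jitter_m: float = 5.0
    fixes_per_day_breeding: int = 4
    flight_km_per_day: float = 800.0
    max_flight_km_per_day: float = 2640.0  # 110 km/h sustained for 24 h
    gateway_lat: float = 64.0              # last staging latitude, below 66.33
    nesting_days: int = 20

    def __post_init__(self) -> None:
        if self.breeding_site[0] <= ARCTIC_CIRCLE_LAT:
            raise ValueError("breeding_site latitude must exceed 66.33 N")
        if self.n_stopovers < 0:
            raise ValueError("n_stopovers must be >= 0")
        for name in ("sd_individual", "sd_residual", "snowmelt_sd", "sd_travel_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if self.device not in ("GPS", "GLS"):
            raise ValueError("device must be 'GPS' or 'GLS'")

    @property
    def mean_arrival_doy(self) -> float:
        return self.mean_departure_doy + self.mean_travel_days

    @property
    def mean_laying_doy(self) -> float:
        return self.mean_arrival_doy + self.prelaying_days

    @property
    def marginal_arrival_trend(self) -> float:
        """Total arrival-over-time trend implied by the scenario (days/yr)."""
        return self.beta_arrival_year + self.beta_arrival_snowmelt * self.snowmelt_trend

    def replace(self, **kw) -> "PopulationScenario":
        return dataclasses.replace(self, **kw)


# --------------------------------------------------------------------------
# event-level generation (ground truth)
# --------------------------------------------------------------------------

def _route(scenario: PopulationScenario):
    """Waypoints winter -> stopovers -> gateway -> breeding and leg lengths.

    Stopovers sit on the great circle between the winter centroid and a
    "gateway" staging point just below the Arctic Circle; the final gateway ->
    breeding leg is flown in a single day so the Arctic Circle crossing date
    is unambiguous.
    """
    wlat, wlon = scenario.winter_centroid
    blat, blon = scenario.breeding_site
    # place the gateway on the winter->breeding great circle at gateway_lat
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        lat, _ = gc_waypoint(wlat, wlon, blat, blon, mid)
        if lat < scenario.gateway_lat:
            lo = mid
        else:
            hi = mid
    glat, glon = gc_waypoint(wlat, wlon, blat, blon, 0.5 * (lo + hi))
    waypoints = [(wlat, wlon)]
    for j in range(1, scenario.n_stopovers + 1):
        frac = j / (scenario.n_stopovers + 1)
        waypoints.append(gc_waypoint(wlat, wlon, glat, glon, frac))
    waypoints.append((glat, glon))
    waypoints.append((blat, blon))
    legs = [
        haversine_km(waypoints[i][0], waypoints[i][1], waypoints[i + 1][0], waypoints[i + 1][1])
        for i in range(len(waypoints) - 1)
    ]
    return waypoints, legs


def generate_site_years(scenario: PopulationScenario, rng: np.random.Generator) -> pd.DataFrame:
    """True snowmelt date per site-year: linear trend plus anomaly."""
    years = np.asarray(scenario.years, dtype=float)
    ybar = years.mean()
    dsm = (
        scenario.snowmelt_mean_doy
        + scenario.snowmelt_trend * (years - ybar)
        + rng.normal(0.0, scenario.snowmelt_sd, size=len(years))
    )
    return pd.DataFrame(
        {
            "population": scenario.population_id,
            "site_id": scenario.population_id,
            "year": scenario.years,
            "snowmelt_doy": dsm,
        }
    )


def generate_events(
    scenario: PopulationScenario, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw true event dates per individual-year from the scenario couplings.

    Returns ``(events, site_years)`` where events has one row per
    individual-year with continuous true departure/arrival/laying days,
    migration distance (km) and travel speed (km/day).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    sites = generate_site_years(scenario, rng)
    years = np.asarray(scenario.years, dtype=float)
    ybar = years.mean()
    dsm = sites["snowmelt_doy"].to_numpy()

    n = scenario.n_individuals
    u = rng.normal(0.0, scenario.sd_individual, size=n)

    _, legs = _route(scenario)
    route_km = float(sum(legs))

    rows = []
    for ix in range(n):
        ind = f"{scenario.population_id}_{ix + 1:03d}"
        for iy, year in enumerate(scenario.years):
            e = rng.normal(0.0, scenario.sd_residual)
            arrival = (
                scenario.mean_arrival_doy
                + scenario.beta_arrival_snowmelt * (dsm[iy] - scenario.snowmelt_mean_doy)
                + scenario.beta_arrival_year * (year - ybar)
                + u[ix]
                + e
            )
            if scenario.departure_tracks_arrival:
                travel = scenario.mean_travel_days + rng.normal(0.0, scenario.sd_travel_days)
                travel = max(travel, 5.0)
                departure = arrival - travel
            else:
                departure = scenario.mean_departure_doy + rng.normal(
                    0.0, scenario.sd_residual
                )
                travel = arrival - departure
                if travel < 3.0:
                    raise GenerationError(
                        f"{ind} year {year}: arrival {arrival:.1f} leaves "
                        f"no time to travel (departure {departure:.1f})"
                    )
            laying = (
                scenario.mean_laying_doy
                + scenario.beta_laying_snowmelt * (dsm[iy] - scenario.snowmelt_mean_doy)
                + scenario.beta_laying_arrival * (arrival - scenario.mean_arrival_doy)
                + rng.normal(0.0, scenario.sd_residual)
            )
            if laying <= arrival:
                laying = arrival + 1.0
            if not departure < arrival < laying:
                raise GenerationError(
                    f"{ind} year {year}: infeasible ordering "
                    f"dep={departure:.1f} arr={arrival:.1f} lay={laying:.1f}"
                )
            md = route_km * (1.0 + rng.normal(0.0, 0.01))
            rows.append(
                {
                    "population": scenario.population_id,
                    "individual_id": ind,
                    "year": year,
                    "snowmelt_doy": dsm[iy],
                    "departure_doy": departure,
                    "arrival_doy": arrival,
                    "laying_doy": laying,
                    "migration_km": md,
                    "travel_speed_km_day": md / travel,
                    "device": scenario.device,
                }
            )
    return pd.DataFrame(rows), sites


# --------------------------------------------------------------------------
# track-level generation
# --------------------------------------------------------------------------

def _offset_deg(lat: float, dx_m: float, dy_m: float) -> tuple[float, float]:
    """Convert metre offsets to (dlat, dlon) degrees at given latitude."""
    dlat = dy_m / 111_320.0
    dlon = dx_m / (111_320.0 * max(math.cos(math.radians(lat)), 1e-6))
    return dlat, dlon


def generate_tracks(
    scenario: PopulationScenario, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate daily GPS fixes for every individual-year of a scenario.

    Returns ``(tracks, ground_truth, site_years)``. Tracks carry columns
    ``individual_id, timestamp, lat, lon, device``; ground truth has the
    whole-day event dates actually used to schedule the fixes (departure <
    arrival < laying per row), plus the nest position.

    Daily schedule per individual-year: winter residency (jitter
    ``winter_jitter_km``) through the departure day; migration legs at ground
    speed <= ``max_flight_km_per_day``/24 km/h through the stopovers, with
    dwell days distributed over stopovers and the pre-Arctic gateway; the
    gateway -> breeding-site leg flown on the arrival day; pre-nesting
    wander (jitter ``prenest_jitter_m``) until laying; then a nesting phase
    with fixes jittered ``nest_jitter_m`` around the nest.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    events, sites = generate_events(scenario, rng)
    waypoints, legs = _route(scenario)
    km_to_gateway = float(sum(legs[:-1]))
    route_km = float(sum(legs))  # the on-track path length, used as MD truth
    if legs[-1] > 18.0 * 120.0:
        raise GenerationError(
            f"gateway -> breeding leg of {legs[-1]:.0f} km cannot be flown in "
            "one day under the 120 km/h plausibility limit; raise gateway_lat"
        )

    ind_rows = []
    truth_rows = []
    jit_deg = scenario.winter_jitter_km / 111.32

    for row in events.itertuples(index=False):
        dep = int(round(row.departure_doy))
        arr = int(round(row.arrival_doy))
        lay = max(int(round(row.laying_doy)), arr + 1)  # rounding must not collide
        if not dep < arr < lay:
            raise GenerationError(
                f"{row.individual_id} year {row.year}: rounded events collide "
                f"(dep={dep}, arr={arr}, lay={lay})"
            )
        travel_slots = arr - dep - 1  # days strictly between departure and arrival
        if travel_slots < 1 or km_to_gateway / travel_slots > scenario.max_flight_km_per_day:
            raise GenerationError(
                f"{row.individual_id} year {row.year}: cannot cover "
                f"{km_to_gateway:.0f} km in {travel_slots} days under the "
                f"ground-speed cap"
            )
        # flight days per pre-gateway leg; shrink the slowest legs if needed
        pre_legs = legs[:-1]
        fdays = [max(1, round(l / scenario.flight_km_per_day)) for l in pre_legs]
        while sum(fdays) > travel_slots:
            order = np.argsort([l / f for l, f in zip(pre_legs, fdays)])
            for i in order:
                if fdays[i] > 1 and pre_legs[i] / (fdays[i] - 1) <= scenario.max_flight_km_per_day:
                    fdays[i] -= 1
                    break
            else:
                raise GenerationError(
                    f"{row.individual_id} year {row.year}: route infeasible "
                    f"in {travel_slots} travel days"
                )
        # dwell split across stopovers and the gateway
        n_sites = scenario.n_stopovers + 1
        dwell = travel_slots - sum(fdays)
        dwell_per = [dwell // n_sites] * n_sites
        for j in range(dwell % n_sites):
            dwell_per[j] += 1

        end_doy = lay + scenario.nesting_days
        year = int(row.year)

        # nest: individual-year spot near the breeding site
        blat, blon = scenario.breeding_site
        nlat_off, nlon_off = _offset_deg(blat, rng.normal(0, 200.0), rng.normal(0, 200.0))
        nest_lat, nest_lon = blat + nlat_off, blon + nlon_off
        # pre-nest wander centre ~1 km from the nest
        plat_off, plon_off = _offset_deg(blat, rng.normal(0, 1000.0), rng.normal(0, 1000.0))
        pre_lat, pre_lon = blat + plat_off, blon + plon_off

        # build the day -> position itinerary
        day_pos: dict[int, tuple[float, float]] = {}
        for d in range(1, dep + 1):
            day_pos[d] = (
                waypoints[0][0] + rng.normal(0, jit_deg),
                waypoints[0][1] + rng.normal(0, jit_deg / math.cos(math.radians(waypoints[0][0]))),
            )
        d = dep + 1
        for i, (f, stay) in enumerate(zip(fdays, dwell_per)):
            a, b = waypoints[i], waypoints[i + 1]
            for j in range(1, f + 1):
                if d >= arr:
                    break
                day_pos[d] = gc_waypoint(a[0], a[1], b[0], b[1], j / f)
                d += 1
            for _ in range(stay):
                if d >= arr:
                    break
                day_pos[d] = waypoints[i + 1]
                d += 1
        # any remaining days wait at the gateway
        while d < arr:
            day_pos[d] = waypoints[-2]
            d += 1

        fixes = []

        def _add_fix(doy: int, lat: float, lon: float, hour: float) -> None:
            date = doy_to_date(year, doy)
            h = int(hour)
            m = int(round((hour - h) * 60)) % 60
            fixes.append(
                (
                    row.individual_id,
                    pd.Timestamp(date.year, date.month, date.day, h, m, tz="UTC"),
                    lat,
                    lon,
                    scenario.device,
                )
            )

        for doy in range(1, arr):
            lat, lon = day_pos[doy]
            _add_fix(doy, lat, lon, 12.0)
        # breeding period: several fixes per day for nest detection; the
        # first breeding fix sits at 06:00 so the single-day gateway ->
        # breeding leg spans >= 18 h and never trips the 120 km/h filter
        npd = scenario.fixes_per_day_breeding
        hours = np.linspace(6.0, 23.0, npd)
        # pre-laying birds wander a cross-shaped foraging circuit of radius
        # prenest_jitter_m, so the daily latitude SD stays far above the
        # nest-stationarity threshold by construction; GPS noise
        # (nest_jitter_m) rides on top of every breeding fix
        w = scenario.prenest_jitter_m
        circuit = [(0.0, w), (w, 0.0), (0.0, -w), (-w, 0.0)]
        for doy in range(arr, end_doy + 1):
            if doy < lay:
                clat, clon = pre_lat, pre_lon
            else:
                clat, clon = nest_lat, nest_lon
            for fi, h in enumerate(hours):
                ex = ey = 0.0
                if doy < lay:
                    ex, ey = circuit[fi % len(circuit)]
                dlat, dlon = _offset_deg(
                    clat,
                    ex + rng.normal(0, scenario.nest_jitter_m),
                    ey + rng.normal(0, scenario.nest_jitter_m),
                )
                _add_fix(doy, clat + dlat, clon + dlon, float(h))

        ind_rows.extend(fixes)
        truth_rows.append(
            {
                "population": scenario.population_id,
                "individual_id": row.individual_id,
                "year": year,
                "departure_doy": dep,
                "arrival_doy": arr,
                "laying_doy": lay,
                "nest_lat": nest_lat,
                "nest_lon": nest_lon,
                "snowmelt_doy": row.snowmelt_doy,
                "migration_km": route_km,
                "device": scenario.device,
            }
        )

    tracks = pd.DataFrame(
        ind_rows, columns=["individual_id", "timestamp", "lat", "lon", "device"]
    )
    truth = pd.DataFrame(truth_rows)
    return tracks, truth, sites


def inject_speed_outliers(
    tracks: pd.DataFrame,
    rng: np.random.Generator,
    n_outliers: int = 1,
    jump_deg: float = 30.0,
) -> pd.DataFrame:
    """Teleport ``n_outliers`` randomly chosen fixes by ``jump_deg`` degrees.

    Used to exercise the 120 km/h speed filter; the displaced rows keep their
    timestamps so the implied speed both into and out of them becomes
    implausible (30 degrees of latitude in a day is ~139 km/h). Each
    individual's first and last fixes are never displaced, so a spike is
    always bracketed by clean neighbours.
    """
    out = tracks.copy()
    ends = out.groupby("individual_id")["timestamp"].agg(["idxmin", "idxmax"])
    eligible = out.index.difference(ends.to_numpy().ravel())
    idx = rng.choice(eligible, size=min(n_outliers, len(eligible)), replace=False)
    lat = out.loc[idx, "lat"]
    out.loc[idx, "lat"] = np.where(lat + jump_deg > 89.0, lat - jump_deg, lat + jump_deg)
    return out


# --------------------------------------------------------------------------
# geolocator degradation
# --------------------------------------------------------------------------

def degrade_to_gls(
    tracks: pd.DataFrame,
    rng: np.random.Generator | None = None,
    noise_sd_lat: float = 1.0,
    noise_sd_lon: float = 0.5,
    equinox_before: int = 14,
    equinox_after: int = 18,
    twilight_deg: float = -6.0,
    truncate_polar_day: bool = True,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degrade GPS daily tracks to geolocator quality.

    Adds Gaussian positional noise, blanks latitudes within the spring
    equinox window [equinox - ``equinox_before``, equinox + ``equinox_after``]
    (closed on both ends), truncates fixes after the individual-year's last
    dark night (light-level positions are undefined during polar day), and
    returns a per-day light record with a dark-night indicator computed from
    the *true* (pre-noise) positions.

    Returns ``(gls_tracks, light_record)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    df = tracks.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    df["_doy"] = ts.dt.dayofyear
    df["_year"] = ts.dt.year

    # light record from true daily mean positions
    daily = (
        df.groupby(["individual_id", "_year", "_doy"], as_index=False)
        .agg(lat=("lat", "mean"))
    )
    daily["dark_night"] = has_dark_night(
        daily["lat"].to_numpy(), daily["_doy"].to_numpy(), twilight_deg
    )
    light = daily.rename(columns={"_year": "year", "_doy": "doy"})[
        ["individual_id", "year", "doy", "dark_night"]
    ]

    if truncate_polar_day:
        last_dark = (
            light[light["dark_night"]]
            .groupby(["individual_id", "year"])["doy"]
            .max()
            .rename("last_dark")
        )
        df = df.join(last_dark, on=["individual_id", "_year"])
        df = df[df["_doy"] <= df["last_dark"].fillna(np.inf)].drop(columns="last_dark")

    if noise_sd_lat > 0:
        df["lat"] = df["lat"] + rng.normal(0.0, noise_sd_lat, size=len(df))
    if noise_sd_lon > 0:
        df["lon"] = df["lon"] + rng.normal(0.0, noise_sd_lon, size=len(df))

    eq = df["_year"].map(march_equinox_doy)
    in_window = (df["_doy"] >= eq - equinox_before) & (df["_doy"] <= eq + equinox_after)
    df.loc[in_window, "lat"] = np.nan

    df["device"] = "GLS"
    return df.drop(columns=["_doy", "_year"]).reset_index(drop=True), light


# --------------------------------------------------------------------------
# snow-cover reflectance series
# --------------------------------------------------------------------------

def generate_snow_series(
    site_id: str,
    year: int,
    melt_midpoint_doy: float = 160.0,
    melt_width: float = 20.0,
    n_pixels: int = 500,
    cloud_prob: float = 0.3,
    water_frac: float = 0.0,
    doy_start: int = 74,
    doy_end: int = 258,
    date_step: int = 2,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-pixel green/SWIR reflectance series with a logistic melt-out.

    Expected snow fraction follows a decreasing logistic with midpoint
    ``melt_midpoint_doy``; ``melt_width`` is the number of days over which the
    expected fraction falls from 90% to 10% (``melt_width <= 0`` gives a hard
    step). Cloud flags are drawn independently per pixel-date; water flags
    mark a fixed leading subset of pixel ids.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if not 0.0 <= cloud_prob < 1.0:
        raise ValueError("cloud_prob must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)

    doys = np.arange(doy_start, doy_end + 1, date_step)
    if melt_width > 0:
        k = 2.0 * math.log(9.0) / melt_width
        p_snow = 1.0 / (1.0 + np.exp(k * (doys - melt_midpoint_doy)))
    else:
        p_snow = np.where(doys < melt_midpoint_doy, 1.0, 0.0)

    n_water = int(round(water_frac * n_pixels))
    pix = np.arange(n_pixels)

    snow = rng.random((len(doys), n_pixels)) < p_snow[:, None]
    cloud = rng.random((len(doys), n_pixels)) < cloud_prob
    green = np.where(
        snow,
        rng.normal(0.75, 0.05, snow.shape),
        rng.normal(0.18, 0.04, snow.shape),
    ).clip(0.01, 1.0)
    swir = np.where(
        snow,
        rng.normal(0.12, 0.03, snow.shape),
        rng.normal(0.30, 0.05, snow.shape),
    ).clip(0.01, 1.0)

    out = pd.DataFrame(
        {
            "site_id": site_id,
            "year": year,
            "doy": np.repeat(doys, n_pixels),
            "pixel_id": np.tile(pix, len(doys)),
            "green": green.ravel(),
            "swir": swir.ravel(),
            "cloud": cloud.ravel(),
            "water": np.tile(pix < n_water, len(doys)),
        }
    )
    return out


# --------------------------------------------------------------------------
# literature slope table
# --------------------------------------------------------------------------

def generate_literature_table(
    n_studies: int = 21,
    true_mean_arrival_slope: float = 0.39,
    true_mean_laying_slope: float = 0.62,
    sd: float = 0.30,
    true_mean_arrival_time_slope: float = -0.47,
    true_mean_snowmelt_time_slope: float = -0.30,
    time_slope_sd: float = 0.90,
    laying_time_coupling: float = 0.6,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Study-level slope table emulating the published-literature dataset.

    Snowmelt-response slopes (arrival, laying vs. snowmelt date) are drawn
    around their stated means with SD ``sd``. Time-trend slopes (days/yr) are
    noisier; laying-date trends are generated as ``laying_time_coupling *
    snowmelt_trend + noise`` so that laying trends, but not arrival trends,
    are explained by snowmelt trends.
    """
    if n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    sm_t = rng.normal(true_mean_snowmelt_time_slope, time_slope_sd, n_studies)
    tbl = pd.DataFrame(
        {
            "study": [f"study_{i + 1:02d}" for i in range(n_studies)],
            "species": [f"species_{i + 1:02d}" for i in range(n_studies)],
            "slope_arrival_snowmelt": rng.normal(true_mean_arrival_slope, sd, n_studies),
            "slope_laying_snowmelt": rng.normal(true_mean_laying_slope, sd, n_studies),
            "slope_arrival_time": rng.normal(
                true_mean_arrival_time_slope, time_slope_sd, n_studies
            ),
            "slope_laying_time": laying_time_coupling * sm_t
            + rng.normal(0.0, 0.5 * time_slope_sd, n_studies),
            "slope_snowmelt_time": sm_t,
        }
    )
    return tbl


# --------------------------------------------------------------------------
# I/O helpers
# --------------------------------------------------------------------------

def site_polygon_geojson(scenario: PopulationScenario, half_width_km: float = 15.0) -> dict:
    """Square WGS84 polygon (lon/lat order) around the breeding site."""
    lat, lon = scenario.breeding_site
    dlat = half_width_km / 111.32
    dlon = half_width_km / (111.32 * math.cos(math.radians(lat)))
    ring = [
        [lon - dlon, lat - dlat],
        [lon + dlon, lat - dlat],
        [lon + dlon, lat + dlat],
        [lon - dlon, lat + dlat],
        [lon - dlon, lat - dlat],
    ]
    return {
        "type": "Feature",
        "properties": {"site_id": scenario.population_id},
        "geometry": {"type": "Polygon", "coordinates": [ring]},
    }
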