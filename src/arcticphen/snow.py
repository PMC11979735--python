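"""Snowmelt-date estimation from per-pixel reflectance series.

Per site and date, each valid (cloud- and water-free) pixel is classified as
snow when its normalised difference snow index, NDSI = (green - SWIR) /
(green + SWIR), exceeds 0.4 (strict inequality). The resulting percent
snow-cover series over the season is smoothed with a penalized B-spline GAM
and the snowmelt date is the first moment the smooth drops below 50% cover,
scanning forward on a 0.1-day grid; later re-crossings from fresh snowfall
are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

logger = logging.getLogger(__name__)

NDSI_SNOW_THRESHOLD = 0.4
SNOWMELT_COVER_PERCENT = 50.0
MIN_DATES_FOR_GAM = 8


class SnowDataError(ValueError):
    pass


def compute_ndsi(green, swir):
    """NDSI = (green - SWIR)/(green + SWIR); NaN where both bands are zero."""
    g = np.asarray(green, dtype=float)
    s = np.asarray(swir, dtype=float)
    if (g < 0).any() or (s < 0).any():
        raise ValueError("reflectances must be non-negative")
    denom = g + s
    with np.errstate(divide="ignore", invalid="ignore"):
        ndsi = np.where(denom > 0, (g - s) / np.where(denom > 0, denom, 1.0), np.nan)
    return float(ndsi) if np.ndim(green) == 0 and np.ndim(swir) == 0 else ndsi


def snow_fraction(obs: pd.DataFrame, ndsi_threshold: float = NDSI_SNOW_THRESHOLD) -> float:
    """Percent of valid pixels classified as snow for one site-date.

    Valid pixels are neither cloud- nor water-flagged and have a defined
    NDSI. Raises :class:`SnowDataError` when no valid pixel remains (callers
    drop the date with a warning).
    """
    ndsi = compute_ndsi(obs["green"].to_numpy(), obs["swir"].to_numpy())
    valid = ~obs["cloud"].to_numpy(bool) & ~obs["water"].to_numpy(bool) & np.isfinite(ndsi)
    if valid.sum() == 0:
        raise SnowDataError("no valid pixels for this site-date")
    return 100.0 * float((ndsi[valid] > ndsi_threshold).sum()) / float(valid.sum())


def build_snow_fraction_series(reflectance: pd.DataFrame) -> pd.DataFrame:
    """Percent snow cover per site-year-date from a pixel reflectance table.

    Dates with no valid pixels are dropped (logged); a site-year in which
    every date drops (e.g. all pixels water-flagged) raises.
    """
    rows = []
    for (site, year, doy), grp in reflectance.groupby(["site_id", "year", "doy"], sort=True):
        try:
            frac = snow_fraction(grp)
        except SnowDataError:
            logger.warning("dropping %s %s doy %s: no valid pixels", site, year, doy)
            continue
        rows.append({"site_id": site, "year": int(year), "doy": float(doy), "percent": frac})
    out = pd.DataFrame(rows, columns=["site_id", "year", "doy", "percent"])
    if out.empty:
        raise SnowDataError("no site-date has any valid pixel")
    return out


@dataclass
class SnowGam:
    """Fitted penalized-spline smooth of percent snow cover vs day of year."""

    result: object
    smoother: BSplines | None
    doy_min: float
    doy_max: float
    alpha: float
    edf: float
    resid_sd: float
    constant: float | None = None  # degenerate flat series need no smooth

    def predict(self, doys) -> np.ndarray:
        doys = np.asarray(doys, dtype=float)
        if self.constant is not None:
            return np.full(doys.shape, np.clip(self.constant, 0.0, 100.0))
        exog = np.ones((len(doys), 1))
        pred = self.result.predict(exog, exog_smooth=doys[:, None])
        return np.clip(np.asarray(pred, dtype=float), 0.0, 100.0)


def fit_snow_gam(
    series: pd.DataFrame,
    basis_dim: int | None = None,
    alphas: np.ndarray | None = None,
) -> SnowGam:
    """Fit a cubic penalized B-spline GAM to one site-year cover series.

    The basis dimension defaults to ``min(10, n_dates // 2)`` and the
    smoothing penalty is chosen by generalized cross-validation over a log
    grid. Fractions are fitted on the percent scale (Gaussian); predictions
    are clipped to [0, 100]. Row order does not affect the fit.
    """
    s = series.sort_values("doy")
    doy = s["doy"].to_numpy(dtype=float)
    y = s["percent"].to_numpy(dtype=float)
    n = len(doy)
    if n < MIN_DATES_FOR_GAM:
        site = series["site_id"].iloc[0] if "site_id" in series.columns else "?"
        year = series["year"].iloc[0] if "year" in series.columns else "?"
        raise SnowDataError(f"{site} {year}: only {n} usable dates (need >= {MIN_DATES_FOR_GAM})")
    if float(np.ptp(y)) < 1e-9:  # flat series: the smooth is that constant
        return SnowGam(None, None, float(doy.min()), float(doy.max()),
                       0.0, 1.0, 0.0, constant=float(y[0]))
    if basis_dim is None:
        basis_dim = int(min(20, max(4, n // 3)))
    if alphas is None:
        alphas = np.logspace(-2, 6, 9)

    smoother = BSplines(doy[:, None], df=[basis_dim], degree=[3], include_intercept=False)
    exog = np.ones((n, 1))
    basis = np.column_stack([exog, smoother.basis])
    pen = np.zeros((basis.shape[1], basis.shape[1]))
    pen[1:, 1:] = smoother.penalty_matrices[0]
    xtx = basis.T @ basis

    best = None
    for alpha in alphas:
        model = GLMGam(y, exog=exog, smoother=smoother, alpha=[float(alpha)])
        try:
            res = model.fit()
        except Exception:  # singular penalty corner cases
            continue
        mu = np.asarray(res.predict(exog, exog_smooth=doy[:, None]), dtype=float)
        rss = float(np.sum((y - mu) ** 2))
        # effective df: tr[(X'X + aS)^-1 X'X] for the penalized Gaussian fit
        try:
            edf = float(np.trace(np.linalg.solve(xtx + alpha * pen, xtx)))
        except np.linalg.LinAlgError:
            edf = float(res.df_model) + 1.0
        edf = min(edf, n - 1.0)
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, float(alpha), res, edf, rss)
    if best is None:
        raise SnowDataError("GAM fit failed for all penalty values")
    _, alpha, res, edf, rss = best
    resid_sd = float(np.sqrt(rss / max(n - edf, 1.0)))
    return SnowGam(res, smoother, float(doy.min()), float(doy.max()), alpha, edf, resid_sd)


def snowmelt_date(
    gam: SnowGam,
    threshold_percent: float = SNOWMELT_COVER_PERCENT,
    grid_step: float = 0.1,
) -> float | None:
    """First day of year the fitted smooth drops below the threshold.

    Evaluated on a ``grid_step``-day grid over the observed window with
    linear interpolation between grid points; scanning is forward only, so a
    re-crossing after fresh snowfall never moves the date. Returns None when
    the smooth never falls below the threshold (site-year excluded
    downstream).
    """
    grid = np.arange(gam.doy_min, gam.doy_max + grid_step / 2, grid_step)
    pred = gam.predict(grid)
    below = pred < threshold_percent
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(grid[0])
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = pred[i - 1], pred[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (threshold_percent - y0) * (x1 - x0) / (y1 - y0))


def estimate_snowmelt(
    reflectance: pd.DataFrame,
    basis_dim: int | None = None,
    grid_step: float = 0.1,
) -> pd.DataFrame:
    """Snowmelt date per site-year from a pixel reflectance table.

    Returns columns ``site_id, year, snowmelt_doy, n_dates, edf, resid_sd``;
    site-years whose smooth never drops below 50% are reported with NaN.
    """
    series = build_snow_fraction_series(reflectance)
    rows = []
    for (site, year), grp in series.groupby(["site_id", "year"], sort=True):
        gam = fit_snow_gam(grp, basis_dim=basis_dim)
        dsm = snowmelt_date(gam, grid_step=grid_step)
        rows.append(
            {
                "site_id": site,
                "year": int(year),
                "snowmelt_doy": np.nan if dsm is None else dsm,
                "n_dates": len(grp),
                "edf": gam.edf,
                "resid_sd": gam.resid_sd,
            }
        )
    return pd.DataFrame(rows)
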