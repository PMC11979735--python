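"""Mixed-model and slope-comparison statistics for phenology data.

The analysis layer fits Gaussian linear mixed models of event dates on the
date of snowmelt or on year, with random intercepts for individual (models
with year as predictor) or for individual and year crossed (all other
models). Candidate fixed-effect structures are compared with AICc computed
from maximum-likelihood fits; the lowest-AICc model is selected and models
within 2 units are flagged informative unless they merely add parameters.
Population-specific slopes from interaction models are recovered as marginal
trends (shared slope plus interaction contrast) with Wald confidence
intervals, and population-level slopes feed ordinary least-squares
"slope-of-slopes" regressions that attribute arrival trends to departure,
distance or travel-speed trends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

logger = logging.getLogger(__name__)

DELTA_AICC_INFORMATIVE = 2.0
MIN_YEARS_FOR_TREND = 5


class StatsError(ValueError):
    pass


class ZeroVarianceError(StatsError):
    pass


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

@dataclass
class LMMFit:
    """A fitted Gaussian (mixed) linear model plus AICc bookkeeping.

    ``k`` counts fixed effects + variance components + the residual variance.
    """

    label: str
    formula: str
    random: tuple[str, ...]
    result: object
    n: int
    k: int
    llf: float
    converged: bool
    singular: bool
    row_index: tuple = ()

    @property
    def params(self) -> pd.Series:
        return self.result.fe_params if hasattr(self.result, "fe_params") else self.result.params

    @property
    def bse(self) -> pd.Series:
        if hasattr(self.result, "fe_params"):
            return self.result.bse.loc[self.result.fe_params.index]
        return self.result.bse

    def cov_fixed(self) -> pd.DataFrame:
        cov = self.result.cov_params()
        names = list(self.params.index)
        return cov.loc[names, names]

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.n)


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: tuple[str, ...] = (),
    random: tuple[str, ...] = ("individual_id", "year"),
    reml: bool = False,
    label: str | None = None,
) -> LMMFit:
    """Fit a Gaussian linear mixed model by maximum likelihood.

    ``fixed`` are patsy terms added to an implicit intercept; ``random``
    names grouping columns each contributing a random intercept. Two or more
    random factors are fitted as crossed random intercepts (variance
    components within a single all-encompassing group). With no random term
    the model collapses to OLS. Singular or non-converged fits are flagged,
    never silently dropped.
    """
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    data = data.dropna(subset=[response]).copy()
    for r in random:
        if data[r].nunique() < 2:
            raise StatsError(f"random factor {r!r} needs >= 2 levels")

    singular = False
    converged = True
    if not random:
        res = smf.ols(formula, data=data).fit()
        n = int(res.nobs)
        k = len(res.params) + 1
        llf = float(res.llf)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(random) == 1:
                md = smf.mixedlm(formula, data=data, groups=data[random[0]].astype(str))
            else:
                vcf = {r: f"0 + C({r})" for r in random}
                md = sm.MixedLM.from_formula(
                    formula,
                    groups=np.ones(len(data)),
                    vc_formula=vcf,
                    re_formula="0" if len(random) > 1 else None,
                    data=data,
                )
            res = None
            for method in (None, "lbfgs", "powell"):
                try:
                    cand = md.fit(reml=reml) if method is None else md.fit(reml=reml, method=method)
                except Exception:
                    continue
                if np.isfinite(cand.llf):
                    res = cand
                    break
            if res is None:
                raise StatsError(f"mixed model failed to fit: {formula}")
        converged = bool(getattr(res, "converged", True))
        # variance components at (numerically) zero mean a singular fit
        vc = _variance_components(res)
        singular = any(v < 1e-8 for v in vc.values())
        n = int(res.nobs)
        k = len(res.fe_params) + len(vc) + 1
        llf = float(res.llf)
    return LMMFit(
        label=label or formula,
        formula=formula,
        random=tuple(random),
        result=res,
        n=n,
        k=k,
        llf=llf,
        converged=converged,
        singular=singular,
        row_index=tuple(data.index),
    )


def _variance_components(res) -> dict[str, float]:
    out = {}
    vcomp = getattr(res, "vcomp", None)
    if vcomp is not None and len(vcomp):
        names = getattr(res.model, "exog_vc", None)
        labels = list(names.names) if names is not None else [f"vc{i}" for i in range(len(vcomp))]
        out.update({lab: float(v) for lab, v in zip(labels, vcomp)})
    cov_re = getattr(res, "cov_re", None)
    if cov_re is not None and getattr(cov_re, "size", 0):
        arr = np.atleast_2d(np.asarray(cov_re))
        for i in range(arr.shape[0]):
            out[f"re{i}"] = float(arr[i, i])
    return out


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 llf + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise StatsError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------

@dataclass
class ModelComparison:
    table: pd.DataFrame           # label, k, llf, aicc, delta_aicc, selected, informative
    fits: dict[str, LMMFit] = field(default_factory=dict)

    @property
    def best(self) -> LMMFit:
        lab = self.table.loc[self.table["selected"], "label"].iloc[0]
        return self.fits[lab]


def model_select(fits: list[LMMFit]) -> ModelComparison:
    """AICc-rank candidate models fitted on the identical row set.

    The lowest-AICc model is selected (ties broken toward fewer parameters);
    candidates within 2 ΔAICc are flagged informative unless they contain
    more parameters than the selected model (uninformative-parameter rule).
    """
    if not fits:
        raise StatsError("no candidate models")
    idx0 = fits[0].row_index
    for f in fits[1:]:
        if f.row_index != idx0:
            raise StatsError("candidates were fitted on different row sets")
    rows = [
        {"label": f.label, "k": f.k, "llf": f.llf, "aicc": f.aicc, "converged": f.converged}
        for f in fits
    ]
    tbl = pd.DataFrame(rows).sort_values(["aicc", "k"], kind="mergesort").reset_index(drop=True)
    tbl["delta_aicc"] = tbl["aicc"] - tbl["aicc"].iloc[0]
    best_k = int(tbl["k"].iloc[0])
    tbl["selected"] = False
    tbl.loc[0, "selected"] = True
    tbl["informative"] = tbl["selected"] | (
        (tbl["delta_aicc"] <= DELTA_AICC_INFORMATIVE) & (tbl["k"] <= best_k)
    )
    return ModelComparison(tbl, {f.label: f for f in fits})


# --------------------------------------------------------------------------
# population-specific slopes (emtrends-style marginal trends)
# --------------------------------------------------------------------------

@dataclass
class SlopeEstimate:
    population: str
    response: str
    covariate: str
    slope: float
    se: float
    ci_low: float
    ci_high: float

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def population_slopes(
    fit: LMMFit, covariate: str, population_col: str = "population"
) -> list[SlopeEstimate]:
    """Per-population marginal slopes from a covariate x population model.

    For the reference population the slope is the covariate main effect; for
    the others the interaction contrast is added, with the standard error
    taken from the coefficient covariance. Confidence intervals are Wald at
    95%.
    """
    params = fit.params
    cov = fit.cov_fixed().to_numpy()
    names = list(params.index)
    if covariate not in names:
        raise StatsError(f"model does not contain covariate {covariate!r}")
    response = fit.formula.split("~")[0].strip()

    # patsy names interactions "cov:C(pop)[T.x]" or "C(pop)[T.x]:cov"
    def _inter_name(level: str) -> str | None:
        for cand in (
            f"{covariate}:C({population_col})[T.{level}]",
            f"C({population_col})[T.{level}]:{covariate}",
        ):
            if cand in names:
                return cand
        return None

    levels = set()
    for nm in names:
        if f"C({population_col})[T." in nm:
            lev = nm.split("[T.", 1)[1].rstrip("]").split("]:")[0]
            levels.add(lev)
    data_levels = None
    model_data = getattr(getattr(fit.result, "model", None), "data", None)
    if model_data is not None and hasattr(model_data, "frame"):
        frame = model_data.frame
        if population_col in frame:
            data_levels = sorted(frame[population_col].astype(str).unique())
    if data_levels is None:
        data_levels = sorted(levels)
        ref = "(reference)"
        all_levels = [ref] + data_levels
    else:
        all_levels = data_levels

    out = []
    z = sps.norm.ppf(0.975)
    for lev in all_levels:
        vec = np.zeros(len(names))
        vec[names.index(covariate)] = 1.0
        inter = _inter_name(str(lev))
        if inter is not None:
            vec[names.index(inter)] = 1.0
        slope = float(vec @ params.to_numpy())
        se = float(np.sqrt(vec @ cov @ vec))
        out.append(
            SlopeEstimate(str(lev), response, covariate, slope, se, slope - z * se, slope + z * se)
        )
    return out


def slopes_to_frame(slopes: list[SlopeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": s.population,
                "response": s.response,
                "covariate": s.covariate,
                "slope": s.slope,
                "se": s.se,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "excludes_zero": s.excludes_zero,
            }
            for s in slopes
        ]
    )


# --------------------------------------------------------------------------
# centring / standardisation
# --------------------------------------------------------------------------

def centre_by_population(
    df: pd.DataFrame, columns: tuple[str, ...], population_col: str = "population"
) -> pd.DataFrame:
    """Subtract population-specific means from the named columns."""
    out = df.copy()
    for c in columns:
        out[c] = out[c] - out.groupby(population_col)[c].transform("mean")
    return out


def standardise(df: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    """Subtract the overall mean and divide by the SD (for slope comparison)."""
    out = df.copy()
    for c in columns:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ZeroVarianceError(f"column {c!r} has zero variance")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


# --------------------------------------------------------------------------
# slope-of-slopes regressions
# --------------------------------------------------------------------------

def _ols_fit(data: pd.DataFrame, response: str, terms: tuple[str, ...], label: str) -> LMMFit:
    rhs = " + ".join(terms) if terms else "1"
    res = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    return LMMFit(
        label=label,
        formula=f"{response} ~ {rhs}",
        random=(),
        result=res,
        n=int(res.nobs),
        k=len(res.params) + 1,
        llf=float(res.llf),
        converged=True,
        singular=False,
        row_index=tuple(data.index),
    )


def _subsets(terms: tuple[str, ...]):
    n = len(terms)
    for mask in range(1 << n):
        yield tuple(t for i, t in enumerate(terms) if mask >> i & 1)


def slope_of_slopes(
    slopes: pd.DataFrame,
    response: str = "slope_arrival",
    predictors: tuple[str, ...] = ("slope_departure", "slope_distance", "slope_speed"),
) -> ModelComparison:
    """Explain population arrival-date slopes by the matching slopes of
    departure date, migration distance and travel speed.

    Ordinary linear models over every subset of the predictors (including
    intercept-only) are AICc-compared; candidates with more parameters than
    populations are dropped with a warning.
    """
    data = slopes.dropna(subset=[response]).copy()
    fits = []
    for terms in _subsets(predictors):
        sub = data.dropna(subset=list(terms)) if terms else data
        if len(sub) < len(data):
            continue  # candidates must share the row set
        k = len(terms) + 2
        if len(data) <= k + 1:
            logger.warning("dropping candidate %s: too few populations", terms or "(intercept)")
            continue
        label = " + ".join(terms) if terms else "intercept_only"
        fits.append(_ols_fit(data, response, terms, label))
    if not fits:
        raise StatsError("no slope-of-slopes candidate is estimable")
    return model_select(fits)


RESPONSES_FOR_SLOPES = {
    "slope_arrival": "arrival_doy",
    "slope_departure": "departure_doy",
    "slope_distance": "migration_km",
    "slope_speed": "travel_speed_km_day",
}


def population_standardised_slopes(
    events: pd.DataFrame,
    covariate: str,
    responses: dict[str, str] = RESPONSES_FOR_SLOPES,
    population_col: str = "population",
    min_years: int = MIN_YEARS_FOR_TREND,
    random: tuple[str, ...] = ("individual_id",),
) -> pd.DataFrame:
    """Population-specific slopes of standardised responses on one covariate.

    For each population, each response is standardised (overall mean/SD over
    that population's analysis rows) and regressed on the centred covariate
    with the given random intercepts, one model per response, so the slopes
    are comparable across responses and populations. Populations observed in
    fewer than ``min_years`` distinct years are skipped for time trends.
    """
    rows = []
    for pop, grp in events.groupby(population_col, sort=True):
        grp = grp.dropna(subset=[covariate, *responses.values()])
        if covariate == "year" and grp["year"].nunique() < min_years:
            logger.info("skipping %s: time series shorter than %d years", pop, min_years)
            continue
        if grp.empty:
            continue
        rec = {"population": pop, "n": len(grp)}
        g = grp.copy()
        g["_cov"] = g[covariate] - g[covariate].mean()
        for slope_name, resp in responses.items():
            g["_resp"] = (g[resp] - g[resp].mean()) / g[resp].std(ddof=1)
            fit = fit_lmm(g, "_resp", ("_cov",), random=random, label=f"{pop}:{resp}")
            rec[slope_name] = float(fit.params["_cov"])
            rec[f"{slope_name}_se"] = float(fit.bse["_cov"])
        rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# laying-date model family
# --------------------------------------------------------------------------

def laying_model(
    records: pd.DataFrame,
    response: str = "laying_doy",
    snowmelt: str = "snowmelt_doy",
    arrival: str = "arrival_doy",
    population_col: str = "population",
    random: tuple[str, ...] = ("year",),
    centre: bool = True,
) -> ModelComparison:
    """Individual-level laying dates explained by snowmelt and own arrival.

    Fits the hierarchical family of models with fixed terms drawn from
    {snowmelt, arrival, population, snowmelt x population, arrival x
    population} (interactions only alongside both parents) plus an
    intercept-only model, with random intercepts for year (individual can be
    added via ``random``), on population-centred laying and arrival dates.
    Collinearity between snowmelt and arrival is flagged when |r| > 0.99.
    """
    df = records.dropna(subset=[response, snowmelt, arrival]).copy()
    multi_pop = df[population_col].nunique() > 1
    if centre:
        df = centre_by_population(df, (response, arrival, snowmelt), population_col)
    r = np.corrcoef(df[snowmelt], df[arrival])[0, 1]
    collinear = abs(r) > 0.99
    if collinear:
        logger.warning(
            "snowmelt and arrival are collinear (r=%.3f); joint models dropped", r
        )

    pop_term = f"C({population_col})"
    candidates: list[tuple[str, tuple[str, ...]]] = [("intercept_only", ())]
    base_terms = [snowmelt, arrival] + ([pop_term] if multi_pop else [])
    for terms in _subsets(tuple(base_terms)):
        if collinear and snowmelt in terms and arrival in terms:
            continue  # design would be singular
        if terms:
            candidates.append((" + ".join(terms), terms))
    if multi_pop:
        for extra in (
            (f"{snowmelt}:{pop_term}",),
            (f"{arrival}:{pop_term}",),
            (f"{snowmelt}:{pop_term}", f"{arrival}:{pop_term}"),
        ):
            parents = {t.split(":")[0] for t in extra} | {pop_term}
            terms = tuple(sorted(parents | set(extra), key=str))
            candidates.append((" + ".join(extra) + " (full)", terms))

    seen = set()
    fits = []
    for label, terms in candidates:
        key = tuple(sorted(terms))
        if key in seen:
            continue
        seen.add(key)
        fits.append(fit_lmm(df, response, terms, random=random, label=label or "intercept_only"))
    cmp_ = model_select(fits)
    cmp_.collinearity_r = float(r)  # type: ignore[attr-defined]
    return cmp_


# --------------------------------------------------------------------------
# literature meta-analysis
# --------------------------------------------------------------------------

@dataclass
class TTestResult:
    mean: float
    t: float
    df: int
    p: float
    n: int


def one_sample_t(values) -> TTestResult:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise StatsError("need >= 3 studies per slope class")
    if np.std(x, ddof=1) <= 1e-12 * (abs(np.mean(x)) + 1.0):
        raise ZeroVarianceError("slopes have zero variance; t-test undefined")
    t, p = sps.ttest_1samp(x, 0.0)
    return TTestResult(float(np.mean(x)), float(t), len(x) - 1, float(p), len(x))


def literature_meta(table: pd.DataFrame) -> dict:
    """t-tests and snowmelt-trend regressions on the literature slope table.

    Tests whether arrival and laying responses to snowmelt, and their time
    trends, differ from zero; then asks (by AICc against intercept-only)
    whether time trends in arrival/laying are explained by the time trend in
    snowmelt.
    """
    out: dict[str, object] = {}
    for col in (
        "slope_arrival_snowmelt",
        "slope_laying_snowmelt",
        "slope_arrival_time",
        "slope_laying_time",
    ):
        if col in table:
            out[f"ttest_{col}"] = one_sample_t(table[col].dropna())
    for resp in ("slope_arrival_time", "slope_laying_time"):
        if resp in table and "slope_snowmelt_time" in table:
            data = table.dropna(subset=[resp, "slope_snowmelt_time"]).reset_index(drop=True)
            fits = [
                _ols_fit(data, resp, (), "intercept_only"),
                _ols_fit(data, resp, ("slope_snowmelt_time",), "snowmelt_trend"),
            ]
            out[f"lm_{resp}"] = model_select(fits)
    return out
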