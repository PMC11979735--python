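"""End-to-end orchestration: simulate -> extract -> snowmelt -> fit.

Every stage reads and writes plain CSV/GeoJSON/JSON artifacts in the run
directory, so stages can be re-run independently and the whole run is
reproducible from (config, seed). All thresholds default to the study
values (120 km/h speed filter, 200 km departure radius, Arctic Circle at
66.33 N, 25.4 m nest stationarity over 3 days, 3 m / >1 day raptor rule,
60 min darkness bouts, NDSI > 0.4, 50% snow-cover crossing) and are echoed
into the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breeding, migration, snow, stats, synthetic, track_io

logger = logging.getLogger(__name__)


def default_scenarios(
    n_individuals: int = 10, years: tuple[int, ...] = tuple(range(2014, 2024))
) -> list[synthetic.PopulationScenario]:
    """Bundled six-population study: five GPS waterfowl-like populations
    spanning a range of snowmelt couplings and arrival trends (trends driven
    by travel speed: departure dates stay flat) and one geolocator population
    with a negative snowmelt coupling."""
    gps = [
        # (id, winter, breeding, beta_arr_snow, beta_lay_snow, direct year effect)
        ("whitefront_kolguev", (52.3, 5.2), (69.0, 49.0), 0.50, 0.57, -0.5),
        ("swan_malozemelskaya", (53.2, 6.5), (68.3, 53.0), 0.38, 0.35, -0.6),
        ("barnacle_kolguev", (53.4, 6.0), (69.2, 48.6), 0.14, 0.31, -0.2),
        ("pinkfoot_adventdalen", (55.5, 9.0), (78.2, 16.0), -0.10, 0.34, -0.7),
        ("buzzard_kolguev", (54.0, 25.0), (69.1, 49.3), -0.15, 0.13, -0.9),
    ]
    out = []
    for i, (pid, wc, bs, b_as, b_ls, b_ay) in enumerate(gps):
        out.append(
            synthetic.PopulationScenario(
                population_id=pid,
                n_individuals=n_individuals,
                years=years,
                winter_centroid=wc,
                breeding_site=bs,
                beta_arrival_snowmelt=b_as,
                beta_laying_snowmelt=b_ls,
                beta_arrival_year=b_ay,
                snowmelt_trend=-0.3,
                departure_tracks_arrival=False,
                mean_departure_doy=95.0,
                mean_travel_days=45.0,
                seed=11 + i,
            )
        )
    out.append(
        synthetic.PopulationScenario(
            population_id="skua_slettnes",
            n_individuals=n_individuals,
            years=years,
            winter_centroid=(-20.0, 5.0),
            breeding_site=(70.95, 28.2),
            n_stopovers=1,
            beta_arrival_snowmelt=-0.27,
            beta_laying_snowmelt=0.0,
            beta_arrival_year=-0.3,
            snowmelt_trend=-0.3,
            departure_tracks_arrival=False,
            mean_departure_doy=95.0,
            mean_travel_days=45.0,
            device="GLS",
            seed=16,
        )
    )
    return out


@dataclass
class RunConfig:
    """Thresholds, generator settings and model lists for one pipeline run."""

    seed: int = 0
    out_dir: str = "run_output"
    # extraction thresholds (study defaults)
    speed_limit_kmh: float = 120.0
    departure_radius_km: float = 200.0
    arctic_lat: float = 66.33
    nest_sd_threshold_m: float = 25.4
    nest_min_days: int = 3
    buzzard_radius_m: float = 3.0
    darkness_min_bout_min: float = 60.0
    ndsi_threshold: float = 0.4
    snow_threshold_percent: float = 50.0
    gls_departure_k: int = 3
    gls_departure_d_min_km: float = 300.0
    # GAM settings
    gam_basis_dim: int | None = None
    gam_grid_step: float = 0.1
    # snow simulation
    snow_n_pixels: int = 150
    snow_cloud_prob: float = 0.3
    snow_melt_width: float = 20.0
    # generator
    n_individuals: int = 10
    years: tuple[int, ...] = tuple(range(2014, 2024))
    # literature table
    literature_n_studies: int = 21
    scenarios: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scenarios:
            self.scenarios = default_scenarios(self.n_individuals, tuple(self.years))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scen = [synthetic.PopulationScenario(**s) for s in raw.pop("scenarios", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k != "scenarios"})
        if scen:
            cfg.scenarios = scen
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        d["years"] = list(self.years)
        return d


def _hash_config(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out: Path) -> None:
    rng = np.random.default_rng(cfg.seed)
    all_truth, all_sites, all_field, polygons = [], [], [], []
    for scen in cfg.scenarios:
        srng = np.random.default_rng(rng.integers(2**31))
        tracks, truth, sites = synthetic.generate_tracks(scen, srng)
        if scen.device == "GLS":
            tracks, light = synthetic.degrade_to_gls(tracks, srng)
            light.to_csv(out / f"light_{scen.population_id}.csv", index=False)
            # geolocators rarely yield laying dates; field data stand in
            fl = truth[["population", "year", "laying_doy"]].copy()
            fl["individual_id"] = truth["individual_id"]
            fl["method"] = "field_direct"
            all_field.append(fl)
        track_io.write_tracks(tracks, out / f"tracks_{scen.population_id}.csv")
        all_truth.append(truth)
        all_sites.append(sites)
        polygons.append(synthetic.site_polygon_geojson(scen))
        # reflectance series, one file per site, melt midpoint = true snowmelt
        refl = []
        for r in sites.itertuples(index=False):
            refl.append(
                synthetic.generate_snow_series(
                    r.site_id,
                    int(r.year),
                    melt_midpoint_doy=float(r.snowmelt_doy),
                    melt_width=cfg.snow_melt_width,
                    n_pixels=cfg.snow_n_pixels,
                    cloud_prob=cfg.snow_cloud_prob,
                    rng=srng,
                )
            )
        pd.concat(refl).to_csv(out / f"reflectance_{scen.population_id}.csv", index=False)
    pd.concat(all_truth).to_csv(out / "ground_truth.csv", index=False)
    pd.concat(all_sites).to_csv(out / "site_years_true.csv", index=False)
    if all_field:
        pd.concat(all_field).to_csv(out / "field_laying.csv", index=False)
    with open(out / "sites.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": polygons}, fh)
    lit = synthetic.generate_literature_table(
        n_studies=cfg.literature_n_studies, rng=np.random.default_rng(cfg.seed + 7)
    )
    lit.to_csv(out / "literature_slopes.csv", index=False)


def stage_extract(cfg: RunConfig, out: Path) -> None:
    phen_parts, lay_parts = [], []
    for scen in cfg.scenarios:
        pop = scen.population_id
        fixes = track_io.read_tracks(out / f"tracks_{pop}.csv")
        light = None
        if scen.device == "GPS":
            fixes_f = track_io.filter_speed_outliers(fixes, cfg.speed_limit_kmh)
        else:
            fixes_f = fixes  # speed rule is for GPS; GLS lats already masked
            light = pd.read_csv(out / f"light_{pop}.csv")
        daily = track_io.daily_average(fixes_f)
        phen = migration.extract_migration_phenology(
            daily,
            population=pop,
            light_record=light,
            radius_km=cfg.departure_radius_km,
            arctic_lat=cfg.arctic_lat,
            gls_k=cfg.gls_departure_k,
            gls_d_min_km=cfg.gls_departure_d_min_km,
        )
        phen_parts.append(phen)
        if scen.device == "GPS":
            lay = breeding.extract_laying_dates(
                fixes_f,
                arrivals=phen,
                population=pop,
                method="gps_goose",
                sd_threshold_m=cfg.nest_sd_threshold_m,
                min_days=cfg.nest_min_days,
            )
            lay_parts.append(lay[["population", "individual_id", "year", "laying_doy", "method"]])
    field_path = out / "field_laying.csv"
    if field_path.exists():
        lay_parts.append(pd.read_csv(field_path))
    pd.concat(phen_parts).to_csv(out / "phenology.csv", index=False)
    pd.concat(lay_parts).to_csv(out / "laying.csv", index=False)


def stage_snowmelt(cfg: RunConfig, out: Path) -> None:
    parts = []
    for scen in cfg.scenarios:
        refl = pd.read_csv(out / f"reflectance_{scen.population_id}.csv")
        parts.append(
            snow.estimate_snowmelt(refl, basis_dim=cfg.gam_basis_dim, grid_step=cfg.gam_grid_step)
        )
    pd.concat(parts).to_csv(out / "snowmelt.csv", index=False)


def stage_fit(cfg: RunConfig, out: Path) -> dict:
    phen = pd.read_csv(out / "phenology.csv")
    lay = pd.read_csv(out / "laying.csv")
    melt = pd.read_csv(out / "snowmelt.csv").rename(columns={"site_id": "population"})

    df = phen.merge(melt[["population", "year", "snowmelt_doy"]], on=["population", "year"])
    df = df.merge(
        lay[["population", "individual_id", "year", "laying_doy"]],
        on=["population", "individual_id", "year"],
        how="left",
    )
    df = df.dropna(subset=["arrival_doy", "departure_doy", "snowmelt_doy"])
    df = stats.centre_by_population(df, ("snowmelt_doy",), "population")
    df = df.rename(columns={"snowmelt_doy": "snow_c"})
    df["year_c"] = df["year"] - df.groupby("population")["year"].transform("mean")
    df.to_csv(out / "analysis_table.csv", index=False)

    results: dict[str, object] = {}
    multi_pop = df["population"].nunique() > 1
    pop_term = "C(population)"

    # (i) snowmelt trend over time, site-year level OLS
    sy = (
        df[["population", "year", "year_c", "snow_c"]]
        .drop_duplicates(["population", "year"])
        .reset_index(drop=True)
    )
    cands = [("intercept_only", ()), ("year", ("year_c",))]
    if multi_pop:
        cands += [
            ("year + population", ("year_c", pop_term)),
            ("year x population", ("year_c", pop_term, f"year_c:{pop_term}")),
        ]
    fits = [stats.fit_lmm(sy, "snow_c", t, random=(), label=lab) for lab, t in cands]
    results["snowmelt_trend"] = stats.model_select(fits)

    # (ii)-(v): arrival/laying vs snowmelt and vs year
    def _family(resp: str, cov: str, random: tuple[str, ...]) -> stats.ModelComparison:
        d = df.dropna(subset=[resp]).reset_index(drop=True)
        cands = [("intercept_only", ()), (cov, (cov,))]
        if multi_pop:
            cands += [
                ("population", (pop_term,)),
                (f"{cov} + population", (cov, pop_term)),
                (f"{cov} x population", (cov, pop_term, f"{cov}:{pop_term}")),
            ]
        fits = [stats.fit_lmm(d, resp, t, random=random, label=lab) for lab, t in cands]
        return stats.model_select(fits)

    results["arrival_snowmelt"] = _family("arrival_doy", "snow_c", ("individual_id", "year"))
    results["arrival_time"] = _family("arrival_doy", "year_c", ("individual_id",))
    results["laying_snowmelt"] = _family("laying_doy", "snow_c", ("individual_id", "year"))
    results["laying_time"] = _family("laying_doy", "year_c", ("individual_id",))

    # population-specific slopes from the interaction models (emtrends-style)
    slope_tables = {}
    for key, cov in (
        ("arrival_snowmelt", "snow_c"),
        ("arrival_time", "year_c"),
        ("laying_snowmelt", "snow_c"),
        ("laying_time", "year_c"),
    ):
        cmp_ = results[key]
        label = f"{cov} x population"
        if multi_pop and label in cmp_.fits:
            sl = stats.population_slopes(cmp_.fits[label], cov)
            slope_tables[key] = stats.slopes_to_frame(sl)
    if slope_tables:
        pd.concat(slope_tables, names=["model"]).reset_index(level=0).to_csv(
            out / "population_slopes.csv", index=False
        )

    # (vi)-(ix): slope-of-slopes mechanism attribution
    for cov, key in (("snow_c", "mechanism_snowmelt"), ("year_c", "mechanism_time")):
        random = ("individual_id", "year") if cov == "snow_c" else ("individual_id",)
        try:
            sl = stats.population_standardised_slopes(df, cov, random=random)
            if len(sl) >= 3:
                results[key] = stats.slope_of_slopes(sl)
                sl.to_csv(out / f"{key}_slopes.csv", index=False)
        except stats.StatsError as err:
            logger.warning("%s skipped: %s", key, err)

    # (x): laying explained by snowmelt and own arrival
    lay_df = df.dropna(subset=["laying_doy"]).reset_index(drop=True)
    if len(lay_df) >= 20:
        results["laying_individual"] = stats.laying_model(
            lay_df, snowmelt="snow_c", arrival="arrival_doy", random=("year",)
        )

    # literature meta-analysis
    lit_path = out / "literature_slopes.csv"
    if lit_path.exists():
        results["literature"] = stats.literature_meta(pd.read_csv(lit_path))

    _write_fit_outputs(results, out)
    return results


def _write_fit_outputs(results: dict, out: Path) -> None:
    aicc_rows = []
    coef_rows = []
    for name, obj in results.items():
        if isinstance(obj, stats.ModelComparison):
            t = obj.table.copy()
            t.insert(0, "analysis", name)
            aicc_rows.append(t)
            best = obj.best
            for term, beta in best.params.items():
                coef_rows.append(
                    {
                        "analysis": name,
                        "model": best.label,
                        "term": term,
                        "estimate": float(beta),
                        "se": float(best.bse[term]),
                    }
                )
        elif isinstance(obj, dict):  # literature report
            lit_rows = []
            for key, val in obj.items():
                if isinstance(val, stats.TTestResult):
                    lit_rows.append(
                        {
                            "test": key,
                            "mean": val.mean,
                            "t": val.t,
                            "df": val.df,
                            "p": val.p,
                            "n": val.n,
                        }
                    )
                elif isinstance(val, stats.ModelComparison):
                    t = val.table.copy()
                    t.insert(0, "analysis", f"literature_{key}")
                    aicc_rows.append(t)
            pd.DataFrame(lit_rows).to_csv(out / "literature_meta.csv", index=False)
    if aicc_rows:
        pd.concat(aicc_rows).to_csv(out / "model_comparison.csv", index=False)
    if coef_rows:
        pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)


STAGES = ("simulate", "extract", "snowmelt", "fit")


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order, writing artifacts and a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                stage_simulate(cfg, out)
            elif stage == "extract":
                stage_extract(cfg, out)
            elif stage == "snowmelt":
                stage_snowmelt(cfg, out)
            elif stage == "fit":
                results = stage_fit(cfg, out)
        except Exception as err:  # annotate with the failing stage
            raise PipelineError(stage, err) from err
    import statsmodels

    manifest = {
        "seed": cfg.seed,
        "config_hash": _hash_config(cfg),
        "config": cfg.to_dict(),
        "stages": list(stages),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
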