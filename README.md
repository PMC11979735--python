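# arcticphen

Migratory birds breeding in the Arctic face a compressed season whose start is
set by snowmelt. Whether a population can lay eggs earlier in early-snowmelt
years depends on whether it can *arrive* earlier — by wintering closer, by
departing earlier, or by travelling faster. `arcticphen` is a reusable,
tested pipeline for this class of movement-ecology questions: it extracts
migration and breeding phenology from tracking data, dates snowmelt from
satellite reflectance series, and fits the mixed-model / slope-comparison
framework that links them — with a first-class synthetic-data generator so
every stage can be validated against known ground truth without any download.

It is aimed at movement ecologists working with Movebank-style GPS or
light-level geolocator (GLS) tracks, study-site polygons, and MODIS-style
per-pixel reflectance tables.

## What it computes

Per individual *i* and year *y* the pipeline extracts:

- **Departure** `Dd`: last spring day within 200 km of the mid-winter
  centroid (GPS) or the onset of sustained displacement from it (GLS);
- **Arrival** `Da`: first daily position above the Arctic Circle (66.33° N;
  GPS) or the first day after the last dark night (GLS);
- **Laying** `Dl`: first of ≥ 3 consecutive days with daily latitude SD
  < 25.4 m (geese), a > 24 h stay within 3 m (raptors), ≥ 1 h darkness bouts
  under the midnight sun (GLS), or field back-calculation from hatch dates;
- **Migration distance** `MD` (cumulative great-circle path over daily
  positions) and **travel speed** `V = MD / (Da − Dd)`.

Per site and year, the **snowmelt date** `D_sm` is the first moment a
penalized-spline GAM fitted to daily percent snow cover — the fraction of
valid pixels with NDSI = (green − SWIR)/(green + SWIR) > 0.4 — drops
below 50%.

The statistics layer fits Gaussian linear mixed models such as

    Da ~ D_sm + P + D_sm × P + (1|ID) + (1|Y)
    Dl ~ D_sm + Da + P + … + (1|Y)

(`P` population, `ID` individual, `Y` year), compares all fixed-effect
subsets by AICc (ML fits; lowest wins, ΔAICc ≤ 2 informative unless merely
adding parameters), recovers population-specific slopes with Wald CIs, and
regresses per-population arrival-date slopes on the matching departure,
distance and speed slopes ("slope of slopes") to attribute arrival trends to
a migration mechanism. A literature module runs the one-sample t-tests and
trend regressions used for cross-study comparison.

## Worked example

```python
import numpy as np
from arcticphen import PopulationScenario, synthetic, track_io, migration, breeding, stats

scenario = PopulationScenario(n_individuals=10, years=tuple(range(2014, 2024)))
tracks, truth, sites = synthetic.generate_tracks(scenario, np.random.default_rng(1))

daily = track_io.daily_average(track_io.filter_speed_outliers(tracks))
phen = migration.extract_migration_phenology(daily, population=scenario.population_id)
lay = breeding.extract_laying_dates(tracks, arrivals=phen, population=scenario.population_id)

df = phen.merge(sites[["population", "year", "snowmelt_doy"]], on=["population", "year"])
df["snow_c"] = df["snowmelt_doy"] - df["snowmelt_doy"].mean()
fit = stats.fit_lmm(df, "arrival_doy", ("snow_c",), random=("individual_id", "year"))

print(f"extracted {len(phen)} migrations, {len(lay)} laying dates")
print(f"mean arrival day of year: {df['arrival_doy'].mean():.1f}")
print(f"arrival ~ snowmelt slope: {fit.params['snow_c']:.3f} "
      f"+/- {fit.bse['snow_c']:.3f} days/day (truth 0.5)")
```

prints

```
extracted 100 migrations, 100 laying dates
mean arrival day of year: 140.3
arrival ~ snowmelt slope: 0.483 +/- 0.049 days/day (truth 0.5)
```

The slope says arrival advances 0.48 days per day of earlier snowmelt; the
generator's true coupling was 0.5, and the Wald CI covers it.

The same run is available from the shell — each stage writes plain CSV/JSON
artifacts plus a run manifest into the output directory:

```bash
arcticphen all --seed 1 --out run1      # simulate → extract → snowmelt → fit
arcticphen fit --seed 1 --out run1      # re-run a single stage
```

Key outputs: `phenology.csv` (Dd/Da/MD/V per individual-year), `laying.csv`,
`snowmelt.csv`, `population_slopes.csv`, `model_comparison.csv` (AICc
tables), `coefficients.csv` and `literature_meta.csv`.

## Layout

| module | role |
| --- | --- |
| `arcticphen.synthetic` | scenario-driven generator: tracks, GLS degradation, snow series, literature tables, ground truth |
| `arcticphen.track_io` | CSV/GeoJSON I/O, 120 km/h speed filter, equinox masking, daily averaging, coverage checks |
| `arcticphen.migration` | winter centroid, departure/arrival dates, migration distance, travel speed |
| `arcticphen.breeding` | nest/laying-date detection (GPS stationarity, darkness bouts, back-calculation), method cross-validation |
| `arcticphen.snow` | NDSI, snow-cover fractions, penalized-spline GAM, 50% crossing |
| `arcticphen.stats` | mixed models, AICc selection, population slopes, slope-of-slopes, literature meta-analysis |
| `arcticphen.pipeline` / `arcticphen.cli` | orchestration, config, manifests, `arcticphen` command |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
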