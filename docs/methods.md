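# Methods

This note documents the models behind `arcticphen`: what the synthetic data
emulate, how each estimator is defined, the numerical choices, and what
passing the test suite does and does not establish about real tracking data.

## 1. Generative model for phenology events

Each `PopulationScenario` describes one population breeding above the Arctic
Circle. Site-year snowmelt dates are

    D_sm(y) = μ_sm + τ·(y − ȳ) + a_y,      a_y ~ N(0, σ_sm²)

with trend `τ` (`snowmelt_trend`, days/yr) and interannual anomaly SD
`σ_sm` (`snowmelt_sd`). Arrival for individual *i* in year *y* is

    Da_iy = μ_a + β_as·(D_sm(y) − μ_sm) + β_ay·(y − ȳ) + u_i + e_iy

with individual random intercept `u_i ~ N(0, σ_ind²)` and residual
`e_iy ~ N(0, σ_res²)`. Laying couples to snowmelt and to the bird's own
arrival:

    Dl_iy = μ_l + β_ls·(D_sm(y) − μ_sm) + β_la·(Da_iy − μ_a) + e'_iy.

Departure either tracks arrival at a roughly constant travel duration
(`departure_tracks_arrival=True`; duration noise σ = 2 d) or is drawn flat
around `mean_departure_doy`, in which case any arrival trend is absorbed by
travel duration and hence travel speed — the configuration used to study
mechanism attribution.

Two identities matter for interpreting fits:

- Because `D_sm` is the only snowmelt term in the arrival equation, a
  regression of arrival on snowmelt estimates `β_as` without bias.
- A regression of arrival on year estimates the **marginal trend**
  `β_ay + β_as·τ` (exposed as `PopulationScenario.marginal_arrival_trend`),
  since the snowmelt trend propagates into arrival. The defaults
  (`β_as = 0.5`, `τ = −1.0` d/yr, `β_ay = 0`) give a marginal arrival
  advance of 0.5 d/yr with both single-covariate models correctly specified;
  a non-zero direct year effect would make the snowmelt-slope estimand a
  blend of the two pathways, which is worth knowing before interpreting
  either coefficient on real data.

Default noise levels — σ_ind = 2 d, σ_res = 3 d, σ_sm = 8 d — are typical
of high-Arctic tracking datasets: individual repeatability of a few days,
within-population spread of about a week, and interannual snowmelt swings of
one to three weeks.

## 2. Track construction

Events are rounded to whole days and a daily itinerary is built per
individual-year:

- **Winter** (1 Jan → departure day): fixes jittered 5 km (SD) around the
  winter centroid, one fix per day at 12:00 UTC.
- **Migration**: stopovers sit on the great circle from the winter centroid
  to a *gateway* staging point at `gateway_lat` (default 64° N, deliberately
  below the Arctic Circle so the day before arrival is never "Arctic").
  Legs are flown at ~800 km/day (never above 2640 km/day, i.e. 110 km/h
  sustained — under the 120 km/h plausibility filter), dwell days are
  distributed over stopovers and the gateway, and the final gateway →
  breeding-site leg is flown entirely on the arrival day. Tracks whose final
  leg cannot be flown in a day, or whose travel window is shorter than the
  route allows, raise a `GenerationError` naming the individual-year.
- **Breeding**: four fixes per day. Pre-laying birds walk a deterministic
  cross-shaped foraging circuit of radius 200 m around a spot ~1 km from the
  eventual nest, so the daily latitude SD is guaranteed to sit far above the
  25.4 m stationarity threshold; from the laying day the bird sits on the
  nest with 5 m (SD) GPS noise, far below it. This makes laying-date
  detection exact on clean tracks by construction, which is the point of a
  ground-truth generator: detector failures then indicate estimator bugs,
  not generator ambiguity.

**Geolocator degradation** adds Gaussian position noise (defaults 1.0° lat,
0.5° lon — the magnitude reported for light-level geolocation), blanks
latitude in the closed window [equinox − 14 d, equinox + 18 d], truncates
each individual-year at its last dark night (light-level positions are
undefined under the midnight sun), and emits a daily dark-night record.
"Dark" means the sun sinks below −6° (civil twilight) at local solar
midnight, evaluated as `lat + declination(doy) − 90 < −6` with a standard
sinusoidal declination approximation; the threshold is configurable.

## 3. Event estimators

- **Winter centroid**: coordinate-wise median of January–February daily
  positions; requires ≥ 10 located days spanning both months (configurable).
- **GPS departure**: last located day on or before 1 July within 200 km of
  the centroid, provided a later position exists; a brief excursion with a
  later return inside the radius therefore postpones departure. The paper of
  record for this rule leaves open whether one or both members of a
  violating pair are intended; here the last *inside* day is used, and the
  spring cutoff is configurable.
- **GLS departure**: first located day opening a run of k = 3 consecutive
  located days all ≥ 300 km from the centroid (previous located day closer).
  Days with equinox-blanked latitude contribute through longitude alone
  (east–west distance at the centroid's latitude), which underestimates
  displacement and so can only delay, never fabricate, a departure. This is
  a deterministic surrogate for the visual inspection used with raw
  geolocator tracks; k and the 300 km floor are configurable. On degraded
  synthetic tracks the mean absolute error is below 2 days at 1° latitude
  noise; the residual error is concentrated in birds departing inside the
  equinox window, a genuine physical limit of the device.
- **Arrival**: first daily latitude > 66.33° N (GPS); last dark night + 1
  (GLS). The GLS proxy is early by however long the bird lingers between the
  latitude of continuous daylight and the Arctic Circle — small for the
  rapid final crossings simulated here and reported for real skuas.
- **Migration distance**: sum of great-circle distances between consecutive
  available daily positions in [Dd, Da]; gaps are implicitly bridged by the
  chord (gaps > 3 d flagged). Distances use the haversine on a sphere of
  radius 6371.0088 km; over the temperate-to-Arctic corridor this tracks a
  WGS84 geodesic to well under 0.5% (tested against an independent Vincenty
  implementation).
- **Speed filter**: consecutive-pair speeds above 120 km/h are resolved
  iteratively to a fixpoint. A fix that violates on both sides is a
  teleporting spike and is removed outright; for an isolated violating pair
  the earlier fix is removed (configurable), a literal reading of "the speed
  required to travel from that to the next position".
- **Nest detection**: geese — first run of ≥ 3 consecutive days with daily
  latitude SD < 25.4 m (degrees × 111,320 m/deg; days with < 2 fixes carry
  no spread information and never qualify); the 25.4 m constant is treated
  as an opaque device-precision threshold. Raptors — first period > 24 h
  with all fixes within 3 m of the period's first fix (a computationally
  bounded reading of "all pairwise distances"). Geolocators — first of ≥ 3
  consecutive days each containing a darkness bout ≥ 60 min while the bird
  is in continuous daylight ("regular" is operationalised as the run length
  r, configurable, since the source does not quantify it).

## 4. Snowmelt dating

Per site-date, pixels flagged cloud or water are excluded; the snow fraction
is the percentage of remaining pixels with NDSI strictly above 0.4. The
annual series (March 15 – September 15) is smoothed with a cubic penalized
B-spline GAM fitted on the percent scale (no link; predictions clipped to
[0, 100]):

- basis dimension `min(20, max(4, n/3))` — large enough that a steep melt-out
  is not systematically smeared (a 10-dimensional basis over a 184-day
  window biases the 50% crossing by over a day on a noiseless logistic
  input, and fails to stay within 2% RMS of it);
- smoothing parameter chosen by GCV over a log-spaced grid, with the
  effective degrees of freedom computed from the penalized hat matrix;
- a perfectly flat series short-circuits to a constant smooth (a Gaussian
  GAM cannot be fitted at zero residual variance);
- the snowmelt date is the first forward crossing below 50% on a 0.1-day
  grid with linear interpolation; later re-crossings (fresh snowfall) are
  ignored. Site-years whose smooth never drops below 50% return no date and
  are excluded downstream.

Because the GAM's family, basis and penalty are not pinned down by any
external specification, they are exposed as configuration; the defaults
above recover a logistic melt-out with midpoint day 160 to ±2 days in ≥ 95%
of replicates at 500 pixels and 30% cloud cover, with no detectable bias.

The synthetic reflectance series draws per-pixel snow states from a
decreasing logistic (width = days from 90% to 10% cover, default 20), with
snow pixels at green ≈ 0.75 / SWIR ≈ 0.12 and bare ground at 0.18 / 0.30,
i.e. NDSI ≈ +0.7 vs −0.25, so band noise essentially never flips the
classification — the difficulty in recovery comes from cloud gaps and
pixel sampling, as it does in MODIS data.

## 5. Statistical layer

- Mixed models are Gaussian, fitted by **maximum likelihood** (not REML)
  whenever AICc comparisons across fixed-effect structures are involved,
  since REML likelihoods are not comparable across fixed effects. Crossed
  random intercepts (individual and year) are fitted as variance components
  within a single all-encompassing group — the standard construction for
  crossed designs in `statsmodels.MixedLM`.
- `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` with `k` = fixed effects + variance
  components + residual variance and `n` = number of rows (not groups).
  The lowest-AICc model is selected; models within 2 ΔAICc are flagged
  informative unless they contain more parameters than the winner.
- Population-specific slopes from interaction models are marginal trends
  (shared slope + interaction contrast) with Wald 95% CIs from the
  coefficient covariance — the large-df behaviour of `emmeans::emtrends`;
  no Satterthwaite/Kenward–Roger correction is applied.
- Year and snowmelt covariates are centred by population-specific means;
  responses entering slope-of-slopes comparisons are standardised (overall
  mean/SD) so slopes are comparable across responses. Populations observed
  in < 5 years are excluded from time-trend models.
- The individual-level laying model family spans all hierarchical subsets of
  {snowmelt, arrival, population, and the two interactions} plus
  intercept-only, with a random year intercept. A published formulation of
  this model lists population both as a fixed effect and as a random
  intercept; that combination is unidentifiable, so the fixed effect is kept
  and the random population intercept dropped. Perfectly collinear snowmelt
  and arrival (|r| > 0.99) are flagged and the joint models skipped.
- The time-trend *coverage* checks fit arrival ~ year with random intercepts
  for individual **and year**: snowmelt anomalies induce year-level
  variation around the trend, and omitting the year intercept (as the
  trend-model formulation of record does) understates the slope SE several-
  fold under these study conditions. The pipeline's descriptive trend models
  keep the individual-only structure for fidelity; the difference is a known
  caveat when interpreting trend CIs on real data.
- Literature meta-analysis: one-sample two-sided t-tests per slope class
  (error on zero variance), and OLS of arrival/laying time-slopes on the
  snowmelt time-slope compared against intercept-only by AICc. The default
  synthetic literature table (21 studies; snowmelt-response slopes mean
  0.39/0.62, SD 0.30; time slopes SD 0.9; laying trends coupled to snowmelt
  trends with coefficient 0.6) reproduces the qualitative pattern that
  laying trends, but not arrival trends, are explained by snowmelt trends.

## 6. Problem sizes and runtime

Tests and the acceptance script use one population of 30 individuals × 15
years (450 individual-years, ~120k fixes) for event-detection and coupling
recovery; 100 replicates for the snowmelt (500 pixels, 30% cloud), coverage
and mechanism checks; and an 8-population design (10 × 10) for mechanism
attribution. The bundled demonstration pipeline (`arcticphen all`) runs six
populations of 10 × 10 with 150-pixel snow series. These sizes keep a full
run near one minute per stage while leaving slope SEs small relative to the
effects studied.

## 7. What the generator does not emulate — limitations

- No Argos-class error structure, tag failure, or partial-season tracks
  (beyond polar-day truncation); the coverage check is exercised but the
  bundled scenarios always pass it.
- Migration is a fixed stopover polyline per population: no route variation
  between individuals or years, no wind drift, no fall migration.
- GLS noise is Gaussian and independent across days; real light-level errors
  are autocorrelated and weather-dependent.
- Snow cover is spatially unstructured (pixels i.i.d. given the logistic),
  so the generator cannot probe errors from patchy melt or very small sites,
  both of which matter for small island study areas.
- Laying dates always exist for GPS birds (no failed breeders or
  non-breeders), so detection specificity is tested only through the
  pre-laying period, not through genuinely nest-less individual-years.
- Passing recovery tests therefore shows the estimators are unbiased and
  correctly implemented under these idealisations, not that they are robust
  to every field pathology; thresholds are exposed in `RunConfig` so
  sensitivity to them can be checked on real data.
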