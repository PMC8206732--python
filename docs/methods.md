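# Methods

This note documents the models inside `wheatclim`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic setup
can and cannot say about real cropping systems.

## Weather generator

The generator emulates the statistical structure of British daily weather
that the downstream analysis relies on, not any particular station record.

* **Precipitation.** Occurrence is a monthly first-order two-state Markov
  chain with transition probabilities `p(wet|dry)` and `p(wet|wet)`; the
  long-run wet-day fraction is `p_wd / (1 + p_wd − p_ww)`. Wet-day amounts
  are gamma distributed with a monthly mean and a single shape parameter
  (default 0.75, giving the right-skewed daily amounts typical of temperate
  rainfall). This is the simplest structure that reproduces wet/dry spell
  clustering; semi-empirical amount distributions of full-featured
  generators are deliberately out of scope.
* **Temperature.** Daily mean = monthly normal + AR(1) residual with
  stationary sd `temp_sd` (default 2.0–2.2 °C) and lag-1 autocorrelation
  0.7, typical of mid-latitude daily anomalies. Tmax/Tmin are the mean ±
  half the monthly diurnal range; Tmax is depressed 1.5 °C on wet days (the
  only temperature–precipitation cross-correlation carried; a full
  cross-covariance matrix is not needed for the analysis and is not
  modelled). Tmax is clamped to ≥ Tmin.
* **Radiation.** Clearness fraction × extraterrestrial radiation from
  standard solar geometry at the site latitude, times 0.6 on wet days.
  Daylength comes from the sunrise equation; latitudes beyond ±66.5° are
  rejected.
* **Calendar.** All years are non-leap (365 days). Generated series span
  1 October to 31 August of the harvest year (335 days), covering the
  20 October sowing.
* **Scenarios.** Change-factor application: monthly temperature deltas are
  additive, precipitation and radiation factors multiplicative — standard
  practice for perturbing a generator with downscaled climate-model
  changes. The baseline scenario (363.8 ppm CO₂, zero deltas, unit factors)
  is an exact identity. Synthetic GCM-like ensembles draw winter/summer
  anchor values per member from configurable normal spreads and
  interpolate monthly by a cosine seasonal weight; defaults give warmer
  (+1.6…+2.8 °C mean), winter-wetter, summer-drier, 2050-like members with
  RCP 4.5 at 487 ppm and RCP 8.5 at 541 ppm. These are stand-ins with
  realistic structure, not downscaled CMIP projections.
* **Seeding.** One RNG stream per year, spawned from the call's seed; one
  seed per (site, scenario) cell derived from a master seed via a stable
  label hash. Runs are bitwise reproducible and order-independent.

## Crop simulator

A daily-timestep source/sink wheat model, deliberately compact.

* **Phenology.** Thermal time above `t_base = 0 °C`; emergence 150 °C·d
  after sowing. Development rate is thermal time × a photoperiod factor
  `1 − sens × (DL_sat − DL)/DL_sat` (clamped to [0, 1], `DL_sat = 15 h`).
  Vernalization accumulates vernal-days with trapezoidal effectiveness
  (full between 0 and 12 °C, ramps to zero at −4 and 16 °C), saturating at
  `vern_full = 40`; final leaf number interpolates 14 → 8 with progress.
  Anthesis at `phyllochron × (FLN + 2.5)` °C·d of development
  (phyllochron 100 °C·d); maturity 650 °C·d later.
  The photoperiod sensitivity default is 0.75. In this linear form the
  parameter is a shape constant, not directly comparable to a daylength
  gene score: values much below ~0.6 leave winter development essentially
  ungated, which makes anthesis advance unrealistically fast under warming
  (≈ 14 d/°C) and lets season shortening overwhelm CO₂ fertilization. At
  0.75 the baseline dry-site anthesis falls in late May and a +2 °C
  warming advances it by ~25 days while 2050-like scenarios still gain
  yield — the directional behavior expected of a vernalizing winter wheat
  with CO₂ fertilization.
* **Canopy and biomass.** LAI grows with leaf stage to a cap of 6.5 and
  senesces linearly over grain fill, accelerated by water stress
  (factor `1 + 2(1 − f_w)`). Interception is Beer's law with `k = 0.45`;
  PAR is 0.5 × global radiation. Daily biomass = RUE (2.2 g DM MJ⁻¹ PAR) ×
  CO₂ factor × intercepted PAR × temperature factor × choking factor. The
  temperature factor ramps 0→1 over 10 °C of *daytime* temperature
  (mean of Tmean and Tmax) above base — using daytime temperature reflects
  when assimilation happens and keeps spring growth from being
  under-predicted. The CO₂ factor is linear: `1 + 0.30 (C − 364)/364`,
  i.e. +30 % RUE at doubling; the 487/541 ppm scenario concentrations sit
  well inside the linear range.
* **Soil water.** `n` 5-cm bucket layers sharing a uniform per-layer
  capacity (`AWC/n`; default AWC 177 mm over 30 layers), full at sowing.
  Rain infiltrates top-down, overflow past the bottom layer is drainage.
  Potential ET is Priestley–Taylor-type (α = 1.26, net radiation 0.6 ×
  global, λ = 2.45 MJ kg⁻¹) split by canopy cover into transpiration
  demand (root zone; roots grow 1 mm per °C·d to the profile bottom) and
  soil-evaporation demand (top 10 cm, throttled by the choking factor of
  the evaporation layers). Extraction is proportional to layer content, so
  stores never go negative and the daily balance closes to floating
  rounding (asserted at 10⁻⁹ mm in tests). Transpiration demand is capped
  by supply but *not* pre-multiplied by the choking factor: the choking
  function throttles assimilation, soil evaporation and senescence, while
  the crop keeps extracting what the profile can deliver — this lets dry
  spells draw the profile down realistically.
* **Choking function.** `f_w = 1` above a fraction of transpirable soil
  water of 0.5, linear to 0 below it. One function serves RUE, soil
  evaporation and senescence.
* **Grain yield.** Ear mass = 0.25 × biomass at anthesis. Potential grain
  number = 100 grains per g ear mass, reduced by the grain-set factor
  (below); grain mass accumulates from post-anthesis assimilation plus
  remobilization of 35 % of anthesis biomass (paced by fill progress) and
  is capped at grain number × 45 mg. Yield is dry matter, 100 g m⁻² =
  1 t ha⁻¹.
* **Grain-set (sink) stress.** Over a ±5-day window around anthesis,
  drought-sensitive cultivars lose grain number linearly with the mean of
  `1 − f_w` (slope 1.0) and heat-sensitive cultivars with accumulated
  degree-days of Tmax above 27 °C (slope 0.05 per °C·d); each response is
  floored at 0.2 and a tolerant cultivar's factor is exactly 1. Slopes and
  floor are free parameters set so that severe window stress yields
  drought/heat index magnitudes of order 0.1.
* **Failed seasons.** Weather ending before anthesis or maturity produces
  an explicit flagged result; summaries exclude failed seasons, count
  them, and flag cells with > 10 % failures. Nitrogen limitation and
  waterlogging are not modelled (no nutrient limitation is imposed by
  design).

## Indices and risk summaries

`WSI = 1 − Yw/Yp`, `DSI = 1 − Ywd/Yw`, `HSI = 1 − Ywh/Yw`, clamped to
[0, 1] only against floating error; a sensitive run out-yielding its
reference raises (it would indicate a simulator bug). Quantiles use linear
interpolation of order statistics at position `1 + q(n−1)` everywhere
(indices, boxplots); the CV uses the n−1 sample standard deviation.
Boxplots report median, quartiles and 10th/90th-percentile whiskers with
outliers defined as points beyond the whiskers. Spatial averages are
unweighted means across sites, percentile-wise for the index percentiles.
Recurrence intervals are `1/(1−q)`.

## Demo fixture and problem sizes

The bundled fixture contrasts a dry southeast site (annual rainfall
~600 mm, latitude 51.8°) with a wet northwest site (~1200 mm, 54.5°),
both on the 177 mm AWC profile with a 20 October sowing — enough to
exercise the north/south water-deficit gradient. Default desk scale is
30 years × 3 members per RCP; the tests run reduced ensembles (6–24
years) and a single long 2000-year baseline run at the dry site for the
exceedance calibration, sizes chosen to keep the whole suite within a few
minutes on one CPU while leaving sampling error well inside the asserted
tolerances.

## What passing tests do and do not show

The generator's defaults are GB-like but synthetic: passing the direction
suites (2050-like scenarios raise mean yield, advance anthesis; dry-site
WSI95 exceeds wet-site WSI95; yield monotone in CO₂; exceedance of the
95th percentile calibrated at 5 %) shows the pipeline reproduces the
expected *qualitative* response structure and its own statistical
definitions. It does not validate magnitudes against observed British
yields or against a calibrated full crop model: baseline yields
(~8 t ha⁻¹) and WSI distributions depend on free parameters that were only
loosely tuned, the drought/heat flowering indices are near zero at the
demo sites because simulated anthesis precedes severe soil drying, and
real station weather, real downscaled projections and cultivar
calibration would all shift the numbers. Results should be read as
demonstrations of the method, not site predictions.

## Numerical conventions

* Determinism: identical inputs give bitwise-identical outputs; all
  stochasticity flows from explicit seeds.
* Degenerate inputs: zero precipitation probabilities give all-dry series;
  zero gamma means give zero rain; a huge, full soil profile makes the
  water-limited run converge exactly to the potential run (the choking
  factor never leaves 1).
* Tie-breaks: anthesis/maturity trigger on the first day the cumulative
  thermal-time threshold is reached; the stress window seeds from the
  five days preceding anthesis (fewer if anthesis follows emergence
  closely).
* CSV round-trips preserve values to 10⁻⁶ (six decimals written); config
  round-trips are exact. Unknown config keys are rejected.
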