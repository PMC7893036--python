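# Methods

This note documents the models, conventions and numerical choices the
package implements, and what its synthetic data can and cannot show.

## Day and daylight conventions

All analysis days are local civil days (midnight to midnight) at a fixed
UTC+2 offset (Botswana keeps no DST). A sensor yields a day's metric
only if at least 80% of its expected records are present (144 for 10-min
body temperature, 288 for 5-min activity, 24 for hourly globes; 80% of
23 within-day fix pairs for GPS). The threshold is configurable
(`DayBoundary.completeness`).

"Daylight" is sunrise-to-sunset from NOAA solar geometry evaluated at
the study centroid (S 24.35°, E 20.62°), accurate to a few minutes at
tropical latitudes (cross-checked in the tests against an independent
Spencer-series implementation). Hourly globe records are stamped at the
hour's start; an hour counts as daylight if its midpoint falls inside
the window. Polar latitudes are rejected.

## Derived daily metrics

- **Body temperature**: daily min, max and amplitude (max − min) over
  the civil day's 10-min records.
- **Microclimate**: collar and reference miniglobes are joined on exact
  hours (hours missing either reading are dropped, never imputed). A
  *cool hour* is a daylight hour with collar more than 0.5 °C below the
  reference (strict inequality); *cumulative cool use* sums the cooling
  depth (reference − collar, positive °C·h) over those hours. The
  source text for the cumulative measure could be read as a signed or
  absolute sum; since it only accumulates over hours where the collar
  is cooler, both readings coincide with the positive-sum definition
  used here.
- **Travel**: haversine displacement (sphere radius 6371.0088 km)
  between consecutive fixes at most 75 min apart; a *travel hour* has
  displacement strictly greater than 1.6 km. No path interpolation —
  the threshold is defined on hourly fixes.
- **Activity**: counts are first normalized by the logger's maximum
  over its entire record (making normalization idempotent and
  cross-logger comparable); the daily total is the sum of relative
  counts and the heat proportion the share in the half-open window
  [10:00, 16:00). An all-zero logger has no defined scale and is
  excluded with an error.

## Mixed models

Every response is modelled as

    g(E[y_ij]) = x_ij' beta + a_i + d_j,
    a_i ~ N(0, sigma_a^2)  (animal),   d_j ~ N(0, sigma_d^2)  (date),

with crossed random intercepts: the date deviate is shared by all
animals on that day. Fixed-effect candidates are the global model
(season + species + interaction), season-only and species-only, with
reference levels drought and gemsbok; an intercept-only null is
available behind a flag but off by default, since the candidate set is
part of the design. Families: Gaussian (body-temperature parameters,
cumulative cool use; total 24 h activity after log transform), binomial
logit for the heat-window proportion (weighted by the daily activity
total, because normalized counts are not integer trials), Poisson log
for daily travel-hour and cool-hour counts.

Estimation is hand-rolled in `thermotrack.glmm` because no installed
Python library fits this combination (crossed random intercepts with
per-group residual variances, weighted binomial GLMMs):

- **Gaussian** — exact marginal likelihood via the Woodbury identity
  with O(n) accumulation of the random-effect cross-products. REML is
  the default for coefficient reporting (with only ~10 animals the ML
  variance bias is material); the maximized *ML* log-likelihood is
  always computed and is what AICc consumes, so model comparison stays
  valid across fixed-effect structures. The optional variance structure
  is a separate residual variance per species-season cell (the default
  for the three body-temperature responses, which are heteroscedastic
  by design) and, optionally, AR(1) residual autocorrelation over days
  within an animal (dense-covariance path, intended for modest n).
- **Binomial/Poisson** — Laplace approximation: penalized IRLS on the
  Henderson system for the conditional modes, Nelder–Mead over the two
  log-SDs. This is the same approximation class as lme4's `glmer`, and
  the tests verify agreement with `glmer` to ~1e-2 on a shared dataset.

Numerical choices: variance parameters are optimized as log-SDs with
bounds [1e-6, 1e3]; indefinite corners of the variance space return a
large penalty rather than crashing; the final (beta, u) solve uses the
Henderson mixed-model equations with iterative refinement for
stability; data that lie exactly in the fixed-effect column space
(zero-noise simulations) short-circuit to the ordinary least-squares
solution with all variance components zero, since any general-path
covariance there is numerically meaningless.

Inference: 95% Wald intervals. Gaussian fits use t quantiles with
containment degrees of freedom — terms constant within animals
(intercept, species) are tested against the animal stratum
(df = animals − 2), the season term against the date stratum, the
interaction against the residual stratum — the same rule nlme and SAS
use; simulation at the study size shows ~95–96% coverage, versus ~88%
for plain normal quantiles. GLMM fits keep normal quantiles (their SEs
are conservative for these data). k for AICc counts fixed effects plus
variance/correlation parameters; n is the number of observation rows.

**Reporting scales.** Each coefficient table carries an explicit tag:
`identity` (°C, °C·h), `log` (log-activity stays on the log scale, so a
seasonal contrast is exp(−(β_season [+ β_interaction])) − 1), 
`response-rate` (Poisson estimates exponentiated: intercept = daily
rate, other terms rate ratios with multiplicative CIs), and
`response-proportion` (logit fits re-expressed as additive
proportion-scale cell effects with delta-method CIs, so cell means
reconstruct by simple addition, e.g. gemsbok non-drought = intercept +
season effect). Marginal means are plug-in predictions at the
random-effect centre (the typical animal and date) transformed through
the inverse link — for log links this is the model-scale median, not
the mean; CIs transform the linear-predictor Wald interval.

Conditional R² follows Nakagawa–Schielzeth:
(σ²_fixed + σ²_animal + σ²_date) / (… + σ²_residual), with σ²_fixed the
variance of the fitted fixed linear predictor and the family-specific
residual variance π²/3 (binomial logit) or ln(1 + 1/λ̄) (Poisson log,
lognormal approximation with λ̄ the mean fitted rate); heteroscedastic
Gaussian fits use the mean of the per-cell residual variances.

## The synthetic-study generator

The generator works daily-truth-first: stage 1 draws, for every
response, the daily GLMM realization (planted fixed effects + animal
intercept + shared daily deviate + residual noise; Poisson draws for
the two count responses); stage 2 renders raw streams that reproduce
those daily values when pushed back through the metrics stage.

Planted defaults are the published coefficient tables of the study the
design emulates — e.g. amplitude (2.2, −0.08, +1.0, −1.03 °C), minimum
body temperature (37.64, −0.13, −0.97, +0.90 °C), travel hours as rate
ratios (0.06 h/day, 1.57, 4.68, 0.37), heat-window proportion (0.13,
+0.05, −0.01, −0.05), log-activity (0.89, −0.07, −0.13, +0.52) — with
the maximum body temperature tied to min + amplitude so the three
thermal responses stay mutually consistent (this fixes its implied
interaction at −0.13, a 0.01 rounding difference from the printed
value). The environmental envelope (reference-globe and dry-bulb
extremes, solar, wind, rainfall totals and rainy-day counts, NDVI)
follows the published seasonal summaries. Random-effect and residual
SDs are not published; defaults were chosen once so that the implied
coefficient CI widths match the published intervals at the study's
sample sizes (e.g. amplitude: animal 0.35, date 0.12, residual
0.5 °C).

Rendering details, chosen so daily metrics are exact:

- **Body temperature**: a two-harmonic cosinor (24 h + 12 h) with
  trough 06:00 and peak 18:00; because the 12 h amplitude is kept below
  an eighth of the 24 h amplitude, the grid extremes stay at those two
  sample points and the daily amplitude is exactly the planted value.
  AR(1) texture (SD 0.08 °C, ρ = 0.6 at the 10-min lag) is added and
  each day affinely mapped back to its planted extremes.
- **Activity**: a crepuscular template (dawn/dusk peaks) with gamma
  jitter, rescaled so the daily total and heat-window share are exact.
  Each logger's record begins with a three-day pre-season lead-in whose
  first sample is a full-scale handling/deployment spike, so the
  per-logger study-maximum normalization constant is known exactly.
  Counts are stored in arbitrary per-logger sensor units (floats).
- **Microclimate**: the collar globe equals the reference globe except
  during a contiguous midday shade bout of exactly the planted number
  of daylight hours, whose per-hour depths (each ≥ 0.6 °C, clearing the
  0.5 °C rule) sum to the planted cumulative use; other hours carry
  N(0, 0.3 °C) sensor noise.
- **GPS**: a correlated random walk (gamma routine steps capped at
  1.45 km, wrapped-normal turning, drift back toward the study core
  beyond 60 km) with the planted number of excursion hours per day
  drawn as steps of 1.8–6 km, so the strict 1.6 km classifier recovers
  the daily travel count exactly.
- **Dropout**: independent 2% per-record missingness by default (the
  normalization spike is never dropped).

With all noise off (`config.zero_noise()`), every derived metric equals
its planted cell mean to numerical precision (count responses use the
rounded planted rate, since integer counts cannot equal a fractional
mean); this is asserted end-to-end in the tests. With default noise two
known, deliberate distortions remain: collar sensor noise tips ~5% of
non-shade daylight hours past the 0.5 °C threshold (inflating cool
hours by ~0.4 h/day and cumulative use slightly — the price of
realistic sensor noise), and dropout thins activity totals by ~2% and
occasionally removes a travel fix or a day's true extreme. None of
these touch the species or season contrasts materially.

What the generator does **not** emulate: behavioural feedbacks between
streams (shade use, activity and travel are drawn independently given
the daily effects), herd structure, mortality/attrition beyond uniform
dropout, NDVI dynamics beyond a per-season constant plus noise, and any
distributional claim about raw accelerometer counts (the gamma-jittered
template is a stand-in, not an inference about the sensor). Passing
recovery tests therefore show that *the pipeline estimates what was
planted under its own assumptions*, not that those assumptions hold for
real collar data.

## Study-design constants

- Seasons: 2013-09-01…2013-11-30 ("drought", preceding wet-season
  rainfall 132 mm) and 2014-09-01…2014-11-30 ("non-drought", 277 mm).
- Default roster: 5 gemsbok + 6 wildebeest (the body-temperature sample
  of the emulated study); recovery of the travel rate ratio uses
  5 + 4, the GPS sample.
- Rainy day: daily rainfall > 0.1 mm (configurable; the source counts
  rainy days without defining one).
- Heat window: [10:00, 16:00), half-open at 16:00.

## Problem sizes

The test suite and the acceptance script run the study at its natural
size (11 animals × 182 days ≈ 2000 animal-days per response; recovery
suites use 20 replicates), which keeps the full suite around a minute
of compute for the models stage. The AR(1) Gaussian path is exercised
on a reduced 4-animal × 60-day design, matching its dense-covariance
implementation's intended scale.

## Known limitations

- AICc values for REML-reported Gaussian fits come from a separate ML
  optimization; for the AR(1) path the ML value is evaluated at the
  REML optimum instead (the difference is far below any ΔAICc = 2
  decision at these sizes).
- Averaging exponentiated estimates (rate ratios) across replicates is
  right-skewed and sits a few percent above the planted ratio by
  Jensen's inequality; the recovery tolerance absorbs this.
- Marginal means on log/logit links are typical-subject predictions;
  population-averaged means would need integration over the random
  effects.
- The binomial weights (daily activity totals, ~2.4 relative units) are
  far smaller than real binomial trial counts, so those SEs are
  conservative by construction.
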