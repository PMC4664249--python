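# Methods

This note documents the models implemented in `heatwave_id`, the
assumptions behind them, the synthetic data they are tested against, and
the numerical and design choices a maintainer would want spelled out.

## Scope and data model

The package works on warm-season records: April 1 through September 30,
exactly 183 days per year regardless of leap years, because February never
enters the season. The day index `t` is 1-based and concatenates seasons
(40 years → 7,320 days; a 43-monitor network → 314,760 monitor-day cells).
`t` is distinct from the Julian day (day of year): the former indexes the
study record, the latter the position in the calendar year. All
computation is in °F; °C appears only in report tables, rounded to two
decimals.

Monitors carry a location (decimal degrees) and a region label. Distances
are great-circle (haversine, Earth radius 6371 km); region membership is
an input column, not a GIS computation.

## Heat index

`heat_index_f` follows the National Weather Service procedure: the simple
Steadman average is computed first, and when it reaches 80 °F the full
Rothfusz regression applies, with the published low-humidity subtraction
(RH < 13 %, 80–112 °F) and high-humidity addition (RH > 85 %, 80–87 °F).
Ties at exactly 80 °F go to the regression. Daily maxima are taken over
each monitor's local calendar date; no minimum number of sub-daily
readings is imposed (some networks require ≥ 18 hourly values — we
deliberately do not, and document it here).

## Imputation models

All three imputers are identities on observed cells and produce fully
observed grids.

### Temporal (per monitor)

    y_t = f1(t) + f2(year_t) + f3(dos_t) + e_t,   e_t ~ N(0, σ²)

with `f1` an AR(1) over the day index (day-to-day persistence and
long-term wander), `f2` a second-order random walk (RW2) over year (one
knot per year), and `f3` an RW2 over day of season 1..183 (one knot per
day, shared across years). RW2 null spaces (level and linear trend) are
re-expressed as explicit fixed effects so every latent block has a proper,
full-rank prior; this is the standard reparameterization and changes
nothing about the fitted curves.

Hyperparameters — the AR coefficient and the three component precisions
relative to σ² — maximize the marginal likelihood with σ² profiled out in
closed form (Nelder-Mead on transformed parameters, warm-started from the
previous monitor's optimum when imputing a whole grid). Components are
read off the posterior (penalized) mean; imputations are the fitted mean
at missing days. Linear algebra exploits the tridiagonal AR(1) precision
(banded Cholesky) with a dense Schur complement for the ~220 smooth-
component coefficients, so one likelihood evaluation costs O(T·p²) and a
40-year monitor fits in a few seconds.

The year effect is dropped and the model refit when fewer than three
years exist, fewer than two seasons carry data, the year-component
variance collapses below 1e-8 of the data variance, or its precision runs
to the optimizer boundary — the same degeneracy (no usable year contrast)
that manifests as a non-positive-definite Hessian in other fitting
engines. Monitors with fewer than 30 observed days are rejected as
unidentifiable.

Known behaviour, confirmed by the validation suite: the temporal model's
predictions shrink toward the seasonal mean, so its mean signed error on
hot cells (> 100 °F) is negative and its extreme-value RMSPE is the worst
of the three methods.

### Spatial (per day)

    y_i = μ_t + e_i,   Cov(e_i, e_j) = sill · exp(−d_ij / range)

Ordinary kriging with an unknown constant day mean and isotropic,
second-order-stationary exponential covariance. Parameters are estimated
by REML separately for each day; the sill profiles out, leaving a
one-dimensional search over the range (bounds 1–5000 km, log scale). The
nugget defaults to zero (exact interpolation at observed sites) and can be
supplied for noisier data. Kriging weights solve the standard system with
the unbiasedness constraint; they sum to one, reproduce constants exactly,
and duplicated coordinates raise an error naming the offending pair.

Fallbacks: a day observed by fewer than two monitors cannot be kriged and
is filled with each missing monitor's own all-years monthly mean of
observed values; a day whose optimizer fails borrows the median parameters
of successfully fitted days in the same calendar month. Both events are
logged with counts.

### Spatio-temporal

    y_it = β0 + β1 · y_{i,t−1} + e_it

with within-day exponential spatial covariance shared across days and days
conditionally independent given the lag. β and the covariance parameters
are estimated jointly by profiled REML: for each candidate range, β is the
GLS solution and the sill profiles out, so the outer search is again
one-dimensional. Pairs with both the value and its lag observed enter the
fit (using already-imputed lags during fitting would entangle estimation
with imputation; we keep them separate).

Imputation runs forward in time within each season: a missing cell gets
β0 + β1·lag plus simple kriging (known mean zero) of that day's observed
residuals — simple rather than ordinary kriging because residuals are
mean-zero by construction, a deliberate distinction from the spatial
model. Lags use observed values when present and the previous day's
imputed value otherwise; the first day of each season has no lag and falls
back to the per-day spatial predictor (or monthly means below two
observed monitors).

## Thresholds and heat waves

Percentiles (80/90/95/97.5) are computed per monitor on the completed
grid over all warm-season days, with linear interpolation between order
statistics (convention differences move thresholds by < 0.1 °F at
n ≈ 7320). The ignore-missing route averages each day's recorded monitors
within a region and takes percentiles of that series.

A regional heat wave is a maximal run of consecutive in-season days where
(1) every monitor in the region is strictly above its own 80th percentile
on every day and (2) every monitor exceeds a regional upper threshold on
at least three days of the run, not necessarily consecutive. "Above" is
strict throughout — the conservative reading. Condition (2) is enforced
per monitor independently. Runs cannot cross season boundaries (the grid
holds no off-season days, and season starts break runs explicitly). In
the ignore-missing variant the same logic applies to the single average
series and missing days break runs.

The regional benchmark is the highest integer-°F candidate (95–120 °F, a
grid covering every plausible benchmark) whose heat-wave set on the
evaluation window (default 2005–2012) is non-empty; the wave count is
non-increasing in the threshold, so a top-down linear scan is exact. A
state-wide "region" is supported simply by giving all monitors one label.

## Validation

`draw_holdout` removes a day-stratified sample of observed cells:
round-half-to-even of fraction × (observed monitors that day), without
replacement, deterministic given the seed. Each imputer runs on the
reduced grid and is scored by RMSPE at the held-out cells — overall, on
cells whose true value exceeds 100 °F (37.78 °C; the subset is defined on
the truth, not the prediction), and per monitor. All methods score the
same single draw, a paired comparison; seed sweeps give replicates.

## Synthetic data

The generator produces ground truth with exactly the structure the models
assume: seasonal sinusoid peaking at day-of-year 196 (mid-July), linear
year trend, small monitor offsets, day-to-day AR(1) anomalies whose
innovations are jointly Gaussian with exponential spatial covariance
(restarted at the stationary distribution each season — seasons are six
months apart), and white nugget noise. Missingness is MCAR within
month × monitor strata: each cell is masked independently with
probability month-rate × monitor-multiplier (capped at 0.95), with the
cool months of the season (April, May, September) missing more often than
June–August, as monitor networks typically show.

Defaults describe a Florida-like network: 43 monitors uniform in
24.5–31 °N × 87.6–80 °W, six latitude-band regions, 1973–2012, seasonal
mean 88 °F, amplitude 10 °F, trend 0.3 °F/decade, AR coefficient 0.65,
innovation sill 9 °F² with 500 km range (daily anomaly fields are
synoptic-scale), nugget 0.5 °F², monitor-offset SD 1 °F, missing rates
0.20 (cool) / 0.05 (warm) with per-monitor multipliers U(0.5, 1.5). The
offset and nugget values are deliberately small: the spatial model assumes
a common day mean with no nugget, and the generator's purpose is to
emulate the structure the analysis assumes; site-level variance is
unpredictable from neighbors by construction, so inflating it degrades
every spatial method against any temporal one and tests the wrong thing.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: bursty missingness (multi-week recording
outages, which hurt temporal imputation far more than independent gaps),
instrument changes or monitor relocation, urban heat-island structure,
skewed/heteroscedastic anomalies, and coastline effects on the covariance.

## Problem sizes and numerical choices

The default validation study runs 43 monitors × 40 seasons with a 10 %
hold-out; parameter-recovery simulations use 500 replicate days (spatial)
and 43 monitors × 10 seasons (spatio-temporal); the pipeline determinism
and anomaly-injection checks use 6–12 monitors over 4–10 seasons. These
sizes give stable estimates while keeping a full test run to minutes.

Tolerances and tie-breaks: kriging systems are solved densely
(LAPACK); a duplicated-coordinate check (≤ 1 m apart) precedes the solve;
constant days short-circuit to the constant (sill 0). Optimizer bounds:
range 1–5000 km, log-precision ±16. The temporal optimizer uses loose
tolerances (0.05 in log-hyperparameters, 0.5 in log-likelihood) because
point imputations are insensitive at that scale. Rounding: CSV writers
emit 4 decimals, so a write-read round trip is exact after one write.
The holdout allocator uses banker's rounding (round-half-to-even), the
numpy default, so 4.3 → 4 cells from 43 observed monitors.

## Known limitations

* The temporal model returns penalized-likelihood point predictions, not
  posterior draws or intervals; imputation uncertainty is not propagated
  into thresholds.
* Per-day REML with ~40 observations estimates the range noisily; the
  median over days is well-behaved (within 25 % in recovery tests) but
  single-day estimates scatter widely.
* The spatio-temporal fit treats days as independent given one lag;
  longer-memory dynamics are absorbed into the lag coefficient.
* The benchmark search assumes integer-°F candidates; data on other
  scales need a different candidate grid.
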