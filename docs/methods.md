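# Methods

This note documents the models, numerical conventions, and design
choices behind `thermoburden`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Study design and likelihood

Each death defines one stratum of a time-stratified case-crossover
design: the case day plus every other day of the same calendar month
and year sharing the case day's day-of-week (3 or 4 referents). The
design is self-matched, so all time-invariant individual covariates
cancel, and the within-month referent window removes seasonality and
secular trends. Conditioning on one event per stratum gives the
partial likelihood

```
l(θ) = Σ_s w_s [ x_case(s)·θ − log Σ_{j∈s} exp(x_j·θ) ]
```

Deaths that share a case date have identical strata; the implementation
therefore evaluates the likelihood on unique case dates with
multiplicity weights `w_s`, which is algebraically identical to the
per-death sum while shrinking the design by roughly the average daily
death count.

The likelihood is maximised by Newton–Raphson with step-halving,
starting at θ = 0, with convergence declared when the relative
log-likelihood change falls below 1e-9 **and** the maximum absolute
gradient falls below 1e-6. Step acceptance tolerates the floating-point
noise floor of the log-likelihood (64·eps·|l|); an absolute tolerance
here causes spurious aborts once |l| reaches ~1e4–1e5. The covariance
is the inverse observed information at the optimum. Two degeneracies
are detected and refused rather than silently returned: a direction
with no within-stratum variation (information singular at θ = 0 →
`NonIdentifiedError`), and perfect separation (information collapsing
at the optimum relative to its value at zero → estimates withheld with
a diagnostic message).

## Basis functions

Exposure, lag, and humidity all use natural (restricted) cubic splines:
cubic between boundary knots, second derivative zero at the boundaries,
linear continuation beyond them. The basis is built from the cubic
B-spline design matrix on the augmented knot vector, projected onto the
null space of the two boundary second-derivative constraints via a
Householder QR; evaluation outside the boundary knots uses the exact
first-order Taylor continuation. This construction reproduces the
standard ns parameterisation used across the epidemiological DLNM
literature bit-for-bit (the test suite pins a frozen reference matrix).

Conventions, chosen where the field's defaults are ambiguous and then
fixed:

* exposure basis **without** intercept (so the cumulative effect at the
  reference temperature is identically zero); lag basis **with**
  intercept (so immediate, lag-0 effects remain representable);
* exposure knots at the 10th/75th/90th percentiles of the observed
  series (linear interpolation between order statistics, so knots are
  bit-reproducible); boundary knots at the series min/max;
* lag knots at equal log-intervals strictly between lag 1 and the
  maximum lag (14 days); lag 0 is excluded from the log grid;
* humidity spline with 3 df (two internal knots at the 33rd/67th
  percentiles).

The cross-basis row for day *t* is
`Σ_{l=0..14} B_exp(T_{t−l}) ⊗ B_lag(l)` (exposure-major column order);
rows in the first 14 days of the series lack a complete exposure
history and are flagged unusable, and strata touching them are dropped
with a logged count.

## Curve reduction, MMT, and relative risks

Summing the lag basis over the integer lags maps the cross-basis
coefficients linearly onto a reduced coefficient vector η; the
cumulative log relative risk between temperatures is a contrast of the
exposure basis applied to η, and its covariance follows by the same
linear map. The minimum-mortality temperature is the argmin of the
cumulative curve on a fixed 0.1 °C grid over the 1st–99th percentile
span of the observed temperatures, with exact ties broken toward the
median temperature; a minimum at either end of the grid is flagged as a
boundary solution. Restricting the search (not only the display) to
P1–P99 avoids extrapolation artifacts in the tails. Relative risks at
the 2.5th/97.5th percentiles versus the MMT carry delta-method 95%
CIs (z = 1.96); evaluations beyond the boundary knots use the natural
linear continuation and are flagged as extrapolated.

## Bias correction

Monthly additive empirical quantile mapping. Fitting: both series are
restricted to the overlap period and linearly detrended there; per
calendar month, offsets are observed-minus-model quantiles on the grid
p = 0.01…0.99. Application: a day's long-term local level (its decade's
mean) is removed and the overlap-period mean level restored, which maps
the day onto the calibration climate under *any* trend shape — a single
straight-line detrend mis-centres a flat-then-ramp trend by several
tenths of a degree. The day's anomaly is located on the model's monthly
quantiles, and the interpolated offset (constant beyond p = 0.01/0.99)
is added to the raw value. Because the level anchor is constant within
any month-year and the quantile map is non-decreasing, within-month
rank order is preserved exactly; because the offset depends only on the
stationary anomaly, the model's warming trend passes through unchanged
(verified to 0.15 °C on a 5.4 °C ramp).

## Attribution and uncertainty

Daily attributable deaths are `D·(1 − e^{−Δ})` with Δ the cumulative
log RR versus the MMT and `D` the average daily deaths of the
observation window, held constant over the projection horizon (no
demographic change or adaptation, deliberately). Days above the MMT
are heat, days below are cold; negative contributions (curve dipping
below the reference) are retained, not truncated, so Monte-Carlo draws
remain unbiased. Decade sums per GCM are ensemble-averaged; AF = AN /
(D × days) × 100. Empirical 95% CIs come from multivariate-normal
draws of η (eigenvalue square root of the reduced covariance, so
exactly-singular covariances are handled), with the MMT held at its
point estimate to isolate coefficient and climate uncertainty from
reference-point jitter; the per-draw × per-GCM decade sums are pooled
and the 2.5th/97.5th percentiles reported. Differences versus the
historical baseline (the average over the 1980s/1990s/2000s) are
computed inside each draw and GCM before pooling, so difference
intervals are internally consistent.

## Synthetic data

The generator emulates the three inputs a national study needs:

* **Weather** — mean 13.5 °C (a realistic national annual mean),
  seasonal cosine of amplitude 14 °C peaking at day-of-year 196, AR(1)
  noise (coefficient 0.7, innovation SD 2.5 °C), humidity clipped to
  [0, 100]%, and a fixed synthetic holiday calendar (weekends plus ten
  fixed dates per year). The simulated P2.5/P97.5 are ≈ −4/+31 °C; a
  symmetric cosine-plus-AR(1) model cannot reproduce the negative skew
  of real national distributions, whose cold tail is heavier.
* **Deaths** — daily counts Poisson with rate
  `baseline · exp(Σ_l w_l f(T_{t−l}))`, where the default truth `f` is
  a piecewise-quadratic inverted J with reference at the 75th
  temperature percentile and cumulative RR 2.0 / 1.3 at the 2.5th /
  97.5th percentiles, and `w` is a front-loaded (heat-like, geometric)
  or mid-lag-peaked (cold-like, Gaussian at lag 6) weight vector
  summing to one. Demographics (age band, sex, education, region) are
  sampled independently of temperature, so subgroup refits can be
  verified without confounding corrections. Desk-scale runs use
  baseline rates of order 10 deaths/day (~30,000 deaths over seven
  years), two orders of magnitude below national registries.
* **Scenarios** — each GCM resamples the observational day-of-year
  climatology (±3-day window), scales anomalies about the seasonal
  mean, adds a constant bias offset (default +1.5 °C) and a linear
  warming ramp that is zero through 2009 and reaches the scenario
  target (1.9 / 2.9 / 5.4 °C for SSP126/SSP245/SSP585) as the 2090s
  decadal mean.

What passing tests therefore show: the estimator recovers a known
smooth surface of realistic magnitude at realistic (scaled-down) sample
sizes, the attribution identities hold exactly, interval procedures
have near-nominal coverage, and the calibration contract holds under
known bias and trend. What they do not show: robustness to heavy cold
tails, spatially heterogeneous exposure, demographic confounding,
registry coding error, or non-additive model biases — none of which the
generator emulates.

## Known limitations

* The minimum of the default truth is shallow (it rises only ~0.008
  log-RR within ±1.5 °C of the reference), so the estimated MMT is
  intrinsically noisy at desk-scale death counts: across repeated
  30,000-death worlds its error has SD ≈ 3 °C with a systematic ≈ −1 °C
  displacement from the spline's inability to represent a quadratic
  exactly. MMT estimates stabilise only at registry-scale samples
  (hundreds of thousands of deaths).
* With the default surface's comparatively shallow heat limb, the
  cold-AF decline under strong warming slightly outweighs the heat-AF
  gain, so the projected late-century *net* burden change is a small
  negative number; a net increase requires a steeper heat limb (MMT
  nearer the 85th–90th percentile), as fitted national curves exhibit.
* One region, one cause category per run; no meta-analytic pooling
  across climate zones; no AIC-driven specification search (a helper
  computes AIC for a given fit, but the primary specification is
  fixed).
* The eCI pools coefficient draws across GCMs (single percentile pool);
  a nested decomposition of coefficient versus climate-model spread is
  not implemented.
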