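# thermoburden

Case-crossover distributed-lag modelling of temperature–mortality
associations, and projection of heat- and cold-attributable death burden
under climate-warming scenarios.

The package is aimed at environmental epidemiologists who want a fully
reproducible, desk-scale implementation of the two-stage design that
national temperature–mortality studies use:

1. **Association stage.** Individual death records are analysed with a
   time-stratified case-crossover design: each death day is compared with
   the other same-weekday days of its calendar month, which removes
   slow time trends, seasonality, and all time-invariant individual
   confounders by construction. The temperature effect is represented by
   a distributed lag non-linear model (DLNM) cross-basis — a tensor of a
   natural cubic spline in temperature (knots at the 10th/75th/90th
   percentiles) and a natural cubic spline in lag (knots at equal
   log-intervals, maximum lag 14 days) — entered into a conditional
   logistic regression together with a holiday indicator and a
   3-df humidity spline. The fit is reduced over the lag dimension to an
   overall cumulative exposure–response curve
   `f*(T)`, from which the minimum-mortality temperature `T_mm`
   (argmin of the curve) and relative risks
   `RR(T) = exp(f*(T) − f*(T_mm))` with delta-method 95% CIs are
   reported.

2. **Projection stage.** Per-GCM daily temperature projections
   (1980–2099, scenarios SSP126/SSP245/SSP585) are bias-corrected
   against the observational series by monthly additive quantile
   mapping that preserves each model's warming trend. Daily attributable
   deaths follow

   `D_attr = D · (1 − e^{−(f*(T) − f*(T_mm))})`

   with `D` the observed average daily death count; days above `T_mm`
   form the heat component and days below the cold component. Sums are
   aggregated by decade and scenario, ensemble-averaged across GCMs,
   expressed as attributable fractions (AF), and differenced against the
   1980–2009 historical baseline. Uncertainty is propagated by Monte
   Carlo resampling of the reduced-curve coefficients (95% empirical
   CIs pooled over draws × GCMs).

Because the death registries and climate products such studies use are
restricted or bulky, the package ships a first-class synthetic-data
module: seasonal + AR(1) daily weather, death records drawn from a
*known* exposure-lag-response surface (an inverted-J curve with
cumulative RR 2.0 at the 2.5th temperature percentile and 1.3 at the
97.5th), and GCM ensembles with additive bias and scenario-dependent
warming ramps. Every stage of the pipeline is therefore testable
against ground truth.

## Worked example

A three-year synthetic study from the shell (configuration in YAML;
one master seed drives every stage):

```sh
$ cat config.yaml
outdir: run
seed: 0
weather_end: "2015-12-31"
obs_end: "2009-12-31"
n_gcms: 3
n_sim: 200
scenarios: {SSP126: 1.9, SSP245: 2.9, SSP585: 5.4}
decades: ["2050s", "2090s"]

$ thermoburden simulate --config config.yaml
$ thermoburden associate --config config.yaml
strata: 16371 (dropped 0); MMT: 24.3 C
$ thermoburden project --config config.yaml
burden rows: 45; diff rows: 18
```

`run/rr_table.csv` then contains the fitted association summary:

```
quantity,value,ci_low,ci_high
MMT_c,24.26,,
RR_P2.5,1.91,1.53,2.39
RR_P97.5,1.26,1.11,1.42
```

The true simulated curve had cumulative RR 2.0 at the 2.5th percentile
and 1.3 at the 97.5th with its minimum at the 75th percentile
(≈ 23 °C): the fit recovers both extreme-temperature risks within their
CIs. `run/burden_differences.csv` holds the projected burden changes
versus the 1980–2009 baseline; for the 2090s:

```
scenario decade component  d_af_pct  d_af_eci_low  d_af_eci_high
  SSP126  2090s      heat      1.50          0.87           2.07
  SSP126  2090s      cold     -2.58         -3.16          -1.81
  SSP245  2090s      heat      2.55          1.58           3.39
  SSP245  2090s      cold     -3.76         -4.57          -2.54
  SSP585  2090s      heat      6.00          3.99           7.55
  SSP585  2090s      cold     -6.21         -7.73          -3.94
```

Heat-attributable fractions rise and cold-attributable fractions fall
with warming, and both responses increase strictly with the steepness
of the scenario ramp (1.9 / 2.9 / 5.4 °C by the 2090s) — the qualitative
signature this class of studies reports.

The same pipeline is available as a library (`thermoburden.synth`,
`.splines`, `.ccfit`, `.curves`, `.calibrate`, `.attribute`,
`.pipeline`); see `docs/methods.md` for the modelling details, numerical
conventions, and known limitations.

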