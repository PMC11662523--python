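# heatmort

Heat–mortality analysis with distributed-lag non-linear models: fit the
short-term association between daily mean temperature and death counts
across many small municipalities, locate the minimum-mortality temperature
(MMT), quantify the mortality burden attributable to heat, and project it to
the end of the century under climate-model scenarios.

The package is aimed at environmental-epidemiology workflows in which the
real inputs — death-register microdata and gridded climate products — are
access-restricted. Every stage therefore comes with a synthetic-data
generator that plants a known exposure–lag–response surface, so the whole
pipeline is testable end to end against ground truth.

## The model

Daily deaths `y_{it}` in municipality `i` follow a conditional Poisson
(case time series) model with stratum-specific baselines,

```
y_{it} ~ Poisson(μ_{it}),   log μ_{it} = ξ_{s(i,t)} + w_{it}·β
```

where strata `s` are `municipality × year × month` (absorbing long-term and
seasonal baseline trends at the finest spatial scale) and `w_{it}` is a
DLNM cross-basis row: the tensor product of a natural cubic spline in
temperature (knots at percentiles of the in-season distribution) and a
natural cubic spline in lag over 0–10 days, summed over the lag window,

```
w_t = Σ_{l=0..L} b_var(x_{t-l}) ⊗ b_lag(l).
```

Conditioning on stratum totals eliminates the `ξ_s` — each stratum's counts
are multinomial with probabilities `∝ exp(w·β)` — which is equivalent to,
but far cheaper than, one Poisson indicator per stratum.

From the fitted `(β, V)` the package derives:

* the overall cumulative exposure–response curve `RR(T) = exp{[w(T)−w(ref)]β}`
  with delta-method CIs, its minimum (the MMT), and lag-specific effects;
* forward attributable fractions `AF_t = 1 − exp(−c(x_t))` for exposures
  above the MMT (where `c` is the cumulative log RR), attributable numbers
  `AN_t = AF_t × mean(deaths_{t..t+L})`, and window aggregates
  `AF% = 100·ΣAN / Σdeaths`, with empirical 95% CIs from 1000 multivariate
  normal coefficient draws;
* trend-preserving bias correction of climate-model temperatures (month-wise
  additive offset + residual rescaling, estimated on the historical overlap);
* projections to 2100: the observed mean death count per seasonal day is
  replicated into each future year (demographics held fixed), the fitted
  curve is log-linearly extrapolated beyond the observed range (the natural
  spline's linear tails), and per-20-year-period impacts are ensemble-means
  across climate models per emission pathway;
* sub-period comparisons (early vs late decades, early vs peak summer) with
  Z-tests on log-RR differences at chosen temperature percentiles.

## Worked example

```python
import numpy as np
import heatmort as hm

cfg = hm.SynthConfig(n_units=20, year_start=1996, year_end=2015, seed=2)
panel = hm.generate_panel(cfg)          # unit, date, tmean, deaths
model = hm.fit_heat_model(panel)        # cross-basis + conditional Poisson
print(f"MMT {model.mmt.mmt:.1f} degC")
t95 = float(np.percentile(model.season_temps, 95))
print(model.curve(temp_grid=[t95]).rr)
```

prints (seed 2):

```
MMT 19.2 degC
[1.94806989]
```

The generator's true MMT is 19.0 °C and the true cumulative RR at the 95th
percentile (28.2 °C) is 2.08: the fit recovers the optimum temperature to a
fraction of a degree and the relative risk within its CI. Continuing with
attribution (`examples/03_attribute_heat_mortality.py`):

```
overall: AN 6822.7 (eCI 5601.4-7929.6)  AF 27.03% (eCI 22.19-31.42%) of 25241 deaths
```

i.e. about 27% of in-season deaths in this synthetic region are
heat-attributable — the synthetic surface is deliberately strong so recovery
tests have signal. `examples/` holds one short script per capability
(simulation/summaries, curve fitting, attribution, projection, sub-period
comparison); each prints what it computes and what the numbers mean.

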