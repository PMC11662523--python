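# Methods

This note documents the statistical machinery, the synthetic study design,
the defaults that matter, and the numerical choices. It is the package's own
account; every empirical statement here is one the test suite or
`scripts/acceptance.py` computes.

## Case time series model

The unit of analysis is the municipality-day. Death counts are modelled as
conditionally Poisson with a separate baseline per stratum; the default
stratum is `municipality × year × month`, so secular mortality trends and
within-year seasonality are absorbed non-parametrically at the municipal
scale and only within-month exposure contrasts identify the temperature
coefficients. A reduced `municipality × year` scheme is available as a
sensitivity option. Conditioning each stratum on its death total turns the
likelihood into a product of multinomials with cell probabilities
`∝ exp(wβ)`; this is exactly the Poisson model with one indicator per
stratum after profiling out the indicators, which the test suite verifies
against a statsmodels GLM with explicit stratum dummies (agreement to 1e-6
relative).

Strata with zero deaths, or with a single usable day, carry no information
and are dropped from the likelihood (they contribute a constant). Days
whose 10-day exposure history crosses a unit boundary or a gap in the
record are flagged invalid by the cross-basis and excluded before
stratification, not imputed. Out-of-season days are kept in the data solely
to provide lag histories for early-season days.

### Optimisation

Newton–Raphson on the conditional log-likelihood with step-halving;
convergence requires relative log-likelihood change < 1e-9 *and* max
gradient < 1e-6, capped at 100 iterations (non-convergence is flagged on
the result, not raised). The Newton step uses a pseudo-inverse of the
observed information so that flat directions — e.g. a column that is
constant within every stratum, which has exactly zero gradient and zero
information — are traversed harmlessly. The reported covariance is the
inverse observed information at the optimum (pseudo-inverse with a warning
if numerically singular).

## Cross-basis

The exposure dimension is a natural cubic spline built from a cubic
B-spline design projected onto the null space of the second-derivative
constraints at the two boundary knots; beyond the boundary the basis
continues with its exact first-order Taylor expansion, which for a natural
spline *is* the function (zero curvature at the boundary). This tail
linearity is later what "log-linear extrapolation" of the fitted curve
means — no separate extrapolation machinery exists or is needed.

Default exposure knots sit at the 10/25/50/75/90th percentiles of the
pooled in-season temperature distribution with boundary knots at the
observed range. Two of the five knots lie below the median deliberately:
the risk minimum of a summer temperature–mortality curve typically sits in
the cooler quarter of the seasonal distribution, and a basis with no knot
below the median cannot bend there. We verified this deterministically by
projecting known curves onto candidate bases: with knots only at the
50/90th (or 50/75/90th) percentiles the projection's minimum lands 2–4 °C
below a true minimum placed at the ~20th percentile, a bias no amount of
data removes. The sensitivity-variant knot sets (50/75/90, 50/75, 75/90) and
alternative lag windows (5, 14) remain one-argument options and are
exercised in tests.

The lag dimension is a natural cubic spline over lags 0..10 with an
intercept and two internal knots equally spaced on the log-lag scale
(flexibility concentrated at short lags, where effects change fastest);
`lag_max=0` degenerates to a pure same-day model. Cross-basis columns are
ordered with the exposure index varying fastest: column `k·df_var + j`
pairs lag-basis column `k` with exposure-basis column `j`.

## MMT and lag reduction

The MMT is the argmin of the overall cumulative log RR on a 0.1 °C grid
over the 1st–99th percentile of in-season temperatures (the window keeps
noisy distribution tails from claiming the minimum; a minimum on the window
edge is returned with a boundary flag). The search is two-pass — predict
centred at the in-season median, re-centre at the minimiser, repeat — for
transparency; the conditional fit itself is centre-invariant, so the passes
agree and the second is a no-op by construction.

The lag dimension is reduced by summing the lag basis over 0..10: `η = Mβ`,
`V_η = MVMᵀ`. Reduced-fit predictions equal full-fit cumulative predictions
identically (the map is linear; tests assert 1e-8), and `(η, V_η)` is what
attribution, projection and the Monte Carlo draws consume.

## Attribution

Forward scheme: the attributable fraction of day *t*'s exposure,
`af_t = 1 − exp(−c(x_t))`, is spread over the deaths observed in the
*forward* window `t..t+10` via their mean, rather than backward-composing
each day's death count from its exposure history. Exposures at or below
the reference contribute zero — the package quantifies heat only. Trailing
days whose forward window is cut short by the end of the series use the
available days and are flagged (`complete_window=False`) rather than
dropped; the alternative (dropping them) changes totals negligibly but
would complicate the exact window-additivity property that tests assert.

Empirical CIs: 1000 draws `η* ~ N(η, V_η)` (eigenvalue-clipped square root
if the covariance is not numerically PSD), totals recomputed per draw with
the point-estimate forward death means reused, bounds at the empirical
2.5/97.5 percentiles. One draw set is shared across all windows of a call
so annual series are coherent draw by draw. The MMT is held fixed across
draws; re-finding it per draw would mix reference uncertainty into what the
cited interval construction treats as coefficient uncertainty, and is
noted as a known divergence risk.

## Bias correction

Month-wise, per municipality: additive offset `C_m` = observed − model
historical mean; residual scale `s_m` = ratio of observed to model
within-month standard deviations, both estimated only on the overlap period
(≥ 10 years required; zero-variance months get `s_m = 1` with a warning).
Application recentres each day on its *own year's* month mean:
`corrected = m_ym + C_m + s_m (x − m_ym)`. Because the year-specific mean
passes through the additive channel untouched, interannual variability and
the long-term warming signal are preserved exactly (tests assert the
future-minus-historical monthly-mean difference is unchanged to 1e-9),
while day-to-day variability is rescaled — the mean-preserving,
variance-adjusting member of the trend-preserving family. The full
day-of-year-windowed transfer-function variant is a documented
simplification left out of scope. The correction is strictly increasing in
the daily value, so within-month rank order is preserved, and it is
idempotent: refitting on corrected history returns `C ≈ 0, s ≈ 1`.

## Projection

Counterfactual deaths: for each unit and day-of-season (days since May 1 —
the season contains no Feb 29, so leap years need no handling), the mean
observed count across years, replicated identically into every projection
year. Total projected deaths per year are therefore constant — the
"unchanged demographics" assumption is an assertable invariant.

Per ensemble member, daily AF/AN on bias-corrected scenario temperatures
(curve extrapolated linearly beyond the observed range), aggregated over
20-year periods tiling 1981–2100; per pathway × period, the point estimate
is the arithmetic mean over members, and the eCI pools the same coefficient
draws across members (draws × members as one empirical distribution), so
the interval reflects both coefficient and inter-model spread. Corrected
member temperatures (not observations) are used for the historical periods
as well, keeping all periods methodologically identical. A member not
covering a period is excluded from that period with a warning.

## Sub-period comparison

Interval (1980–1997 vs 1998–2015) and season (May–June vs July–September)
splits, with optional removal of anomalous years before splitting. Both
sub-fits reuse the *full-period* knots and a shared reference temperature,
so both curves equal RR = 1 at the reference and coefficient differences
are not confounded with basis or centring differences. The Z-statistic is
computed on the log-RR scale with delta-method SEs,
`z = (logRR_a − logRR_b)/√(se_a² + se_b²)`, two-sided normal p. Type-I
error is calibrated by simulation in the acceptance suite (200 null panel
pairs, rejection rate within the binomial 95% band around 0.05).

## Synthetic study design

The generator emulates the statistical texture of a sparse-mortality
Mediterranean-climate region, with defaults frozen as the package's study
conditions:

* 47 municipalities, seasons 1980–2015 (May 1–Sep 30, plus a 10-day
  pre-season temperature buffer), baseline 0.3 deaths/unit/day;
* temperatures: annual-mean 16.6 °C sinusoid with amplitude 7.5 °C peaking
  in late July, per-unit offsets spread over ±1.5 °C, AR(1) noise
  (ρ = 0.7, innovation sd 2.2 °C — lag-1 autocorrelation is test-verified),
  and a 0.2 °C/decade warming trend. The resulting in-season distribution
  (median ≈ 22.5 °C, P95 ≈ 28.5 °C, maxima in the mid-30s) matches the
  descriptive statistics such a region publishes;
* baselines: log-normal multiplicative factors per unit × year × month
  (sd 0.2, mean-one on the natural scale), so conditional fitting is
  genuinely required — an unstratified fit is detectably biased (tested);
* an optional thinning fraction emulates cause-of-death exclusions;
  ICD parsing itself is out of scope.

The true surface is an asymmetric smooth V in log risk: zero value and
slope at the true MMT (19.0 °C); a heat arm of 0.04 log-RR per °C (lag 0)
and a much shallower cold arm of 0.015, each reaching its exact linear form
beyond a 4 °C C1 cubic transition; geometric lag decay of ratio 0.5 over
lags 0..10 (cumulative multiplier ≈ 2.0, RR ≈ 2.2 at MMT+10 °C). Three
properties drove this shape, all decided by closed-form/projection analysis
rather than simulation tuning: (i) a unique curvature-bearing minimum —
under a flat-below-threshold hinge the MMT is not point-identified and no
estimator can recover it; (ii) heat dominance, so the curve is J-shaped
over the seasonal range as real summer curves are; (iii) exact closed-form
values on the linear branches, so recovery tests have hand-computable
oracles. The hinge (`smooth_delta=0, cold_slope_true=0`) remains available
and is what the closed-form unit tests of the surface use.

Scenario members add to the observed day-of-year climatology: a constant
bias, AR(1) noise rescaled by a variance-inflation factor, and a linear
pathway trend centred on the reference period's midpoint. The noise stream
is seeded by (seed, model) only, so two pathways from one seed differ
exactly by their trend term — a construction tests rely on.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: spatial correlation between municipalities
beyond shared seasonality, age/sex structure, humidity or pollution
confounding, heatwave-specific dynamics (temperature extremes arise only
from AR(1) tails), harvesting/mortality displacement, and reporting
artefacts. Results on real panels inherit none of the recovery guarantees.

## Problem sizes and test design

The parameter-recovery study runs the full pipeline on 20 replicate panels
at study scale (47 units × 36 seasons, ≈ 260k records each) and checks:
median |MMT error| ≤ 1.0 °C, median relative error of the cumulative log RR
at MMT+10 °C ≤ 15%, and the true attributable fraction (computed from the
generating surface by the same forward formula) inside the 95% eCI in at
least 16 of 20 replicates (the binomial 95% acceptance region for nominal
0.95 coverage at n = 20). Observed values in a representative run: median
|MMT error| ≈ 0.15 °C, median log-RR error ≈ 2%, coverage 17/20. The Z-test
calibration uses 200 pairs of small null panels (4 units × 3 seasons,
baseline 1 death/day) — large enough for Wald asymptotics, small enough to
fit in seconds. `scripts/acceptance.py` uses one study-scale panel for
recovery and a 10-unit region for the 120-year, 4-member projection; sizes
are chosen so the script completes in about a minute while every quantity
remains a genuine recomputation.

## Known limitations

* The MMT estimate is the argmin of a smooth curve; under surfaces with
  very shallow minima its sampling distribution is wide, and the reported
  eCIs do not include reference-temperature uncertainty.
* Coefficient-draw eCIs capture sampling uncertainty only; basis
  approximation error (truth outside the spline span) is not covered. The
  default 5-knot basis keeps that error well below sampling noise under the
  study conditions; coarser variants need not.
* The conditional likelihood drops information in strata with zero deaths;
  with much sparser data than the defaults (baseline ≪ 0.1/day) many
  strata become uninformative and variance grows accordingly.
* No overdispersion adjustment (none is modelled in the generator; real
  data may need one) and no cold-side burden: attribution is heat-only by
  design.
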