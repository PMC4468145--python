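# Methods

`ozmort` implements a city-level time-series analysis of the short-term
association between ambient ozone and daily mortality, focused on one
question: is the concentration-response (C-R) relationship linear, and
if not, where is the threshold below which no adverse effect is seen?

## Statistical model

For one city, the daily count of non-accidental deaths (age >= 30)
`Y_t` is modelled as Poisson with log link and a log-population offset:

```
Y_t ~ Poisson(mu_t)
log mu_t = log N_year(t) + g(o3_t) + s_temp(temp_t; 6 df) + s_rh(rh_t; 3 df)
         + gamma * pm10_t + s_time(t; 2 df / year)
         + warm_t + year_t + dow_t + holiday_t
```

where `o3_t` is the lag0-1 moving average of daily mean ozone (ppb, the
mean of same-day and previous-day concentrations), temperature enters at
lag 0, and all smooth terms are *unpenalised* natural cubic regression
splines with interior knots at equally spaced quantiles and boundary
knots at the observed extremes. The exposure term `g` takes one of three
forms on identical rows:

* **linear** — a single per-ppb slope;
* **spline** — a 3-df natural cubic spline;
* **threshold** — two hinge terms, `min(o3, t)` and `max(o3 - t, 0)`,
  giving distinct per-ppb slopes below and above a candidate
  threshold `t`.

Fits use iteratively reweighted least squares with convergence declared
when the relative deviance change falls below 1e-9 (at most 100
iterations; non-convergence is always flagged, never silent). The
log-likelihood includes the `-ln y!` constant, so AIC = 2k - 2 ln L is
comparable across exposure forms, and `k` is the exact design column
count because no penalisation is involved.

### Why fixed-df splines rather than penalised smoothers

The historical analyses of this design used penalised GAM smoothers.
Here the degrees of freedom that matter scientifically are fixed a
priori (3 df for ozone, 2 df per year for the time trend), and fixed
bases make the AIC and the nested-model deviance test exact, with
integer degrees of freedom and no effective-df ambiguity. The cost is
that *absolute* AIC values are not comparable with penalised-smoother
output; all decisions therefore rest on AIC differences, deviance
differences and curve shapes, which are robust to this choice.
Temperature and humidity df (6 and 3) are not dictated by the study
design; both are configuration knobs and sensitivity over 3-8 df is a
config edit.

## The three-criterion non-linearity rule

A city is declared to have a non-linear C-R relationship (hence a
candidate threshold) when, comparing the spline against the linear
exposure model on identical rows:

1. dAIC = AIC(spline) - AIC(linear) < 0;
2. the deviance difference is significant at alpha = 0.05 against
   chi-square with df = k_spline - k_linear; and
3. the fitted curve is J- or U-shaped.

Shape is judged visually in the older literature; here it is
operationalised: on a 1-ppb grid spanning the observed exposure, with
log relative rate referenced to the 5th exposure percentile (a stable,
data-rich reference), the central-difference derivative must be <= 0 at
the 10th percentile of exposure and > 0 at the 90th, with the curve
minimum strictly inside the grid. Curves whose probe derivatives are
below 1e-5 per ppb are additionally flagged borderline rather than
silently forced into a class. A degenerate flat curve (max |log RR| <
1e-10) is classed `other`.

## Threshold search and bootstrap CI

For qualifying cities, one Poisson model per integer threshold t in
10-60 ppb is fitted (the confounder block bit-identical across the
grid; only the two hinge columns change) and the min-AIC t is the
estimate, ties breaking to the smaller t. Grid points whose fit fails
to converge are excluded and logged; >20% failures raises a warning.
Slopes below/above the selected t are reported as excess mortality per
1 ppb, `100 (exp(beta) - 1)` with CI endpoints transformed from
beta +/- 1.96 SE.

The 95% CI for t is a percentile bootstrap: each cycle resamples
analysis day-rows with replacement (temporal dependence deliberately
ignored — the resampling unit is the observation, matching the
established procedure), re-runs the min-AIC search on
[t0 - 10, t0 + 10] ∩ [10, 60], and records the re-selected t;
non-convergent cycles are dropped, and the 2.5th/97.5th percentiles of
the recorded thresholds form the interval. Everything is reproducible
given the seed. Inside the bootstrap, each grid fit is warm-started
from the original-data solution at the same t (and from the
neighbouring grid point within a cycle); warm starts change only the
optimisation path, not the convex-likelihood optimum.

Two caveats worth knowing: percentile intervals for a grid-constrained
argmin need not contain the point estimate, and for very strong signals
they over-cover (the discrete draw distribution is wider than the
estimator's sampling error) — behaviour visible in the coverage
experiments below.

## Pooled multi-city model

Cities are pooled with a shared confounder design (one time spline over
the combined span, shared indicator coding, per-city lag averaging so
no window crosses a city boundary) and a Gaussian random intercept per
city. The marginal likelihood is maximised by a Laplace approximation:
penalised IRLS for the joint (fixed, random) mode with a ridge penalty
1/sigma^2 on the city block, then a bounded scalar search over
log sigma^2 of

```
l(beta, u) - u'u / (2 sigma^2) - (m/2) log sigma^2 - (1/2) log det(C'WC + I/sigma^2)
```

With one random effect per city and thousands of observations per city
the Laplace error is negligible; a `fixed_city` mode (ordinary Poisson
with city dummies) provides an exact-likelihood fallback and is the
route on which deviance-difference p-values are reported. AIC for the
random-intercept model counts fixed effects plus one variance
component. The deviance p-value is reported as NaN under the Laplace
route rather than pretending the chi-square reference applies.

## Synthetic data generator

The generator produces city series with the structure the analysis
assumes, so every stage is testable without access data. Defaults
describe a mid-size metropolitan study city:

| component | default | rationale |
|---|---|---|
| population | 2,000,000, constant | mid-size study city |
| baseline log-rate beta0 | -10.5 (~55 deaths/day) | between the mid-size study cities (~49-69 deaths/day) |
| temperature | 14 +/- 10 degC annual sinusoid + AR(1) (phi 0.7, sd 2) | temperate-coastal seasonal cycle |
| ozone | linear in temperature + AR(1) noise, floored at 0; target mean 25, sd 12 ppb, corr ~0.6 with temperature | photochemistry proxy; observed city means 22-29 ppb |
| PM10 | lognormal, mean 50 sd 30 ug/m3, corr 0.4 with ozone | observed 14-64 ug/m3 range |
| humidity | 63 +/- 13%, clipped to [0, 100] | observed range |
| temperature effect | quadratic, 3e-4 per (degC - 20)^2 | U-shaped temperature-mortality curve |
| calendar effects | dow within +/-1.5%, holiday +2%, warm season -3%, trend -2e-5/day | small realistic nuisance structure |
| ozone effect | none / linear(slope) / hockey(t*, b_below, b_above), acting on the lag0-1 average | matches the default analysis lag |

The hockey scenario used throughout the experiments is
`t* = 25 ppb, slope_below = -0.002, slope_above = 0.003` per ppb. The
below slope is negative because that is what the observed city-level
C-R curves show below their thresholds (about -0.43 to -0.08 % per
ppb); a flat below-segment would make the curve only weakly J-shaped
and the kink poorly identified. The baseline of ~55 deaths/day places
the threshold estimator in the regime the experiments are designed to
probe: about 90-95% of estimates within +-3 ppb with a small
heavy-tailed remainder, which is also the regime in which percentile
CIs neither systematically miss nor trivially always cover.

What the generator does *not* emulate: overdispersion, influenza
epidemics and mortality displacement, multi-pollutant chemistry,
monitor-level measurement error, and missing data patterns. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness of the
substantive findings to violations of them.

## Experiment sizes

Simulation experiments are sized to run on a single CPU in minutes:

* threshold recovery: 100 independent ten-year cities;
* bootstrap coverage: 50 replicates with B = 120 resampling cycles
  (the production default remains B = 5000; B enters the percentile
  CI only through order-statistic resolution, and 120 draws resolve
  the 2.5th/97.5th percentiles of an integer-valued statistic
  adequately for a coverage experiment);
* false-positive control: 200 ten-year cities with a genuinely linear
  effect (slope 8e-4 per ppb);
* pooled experiments: 4-6 cities x 4 years.

## Numerical choices and degenerate inputs

* IRLS start: zero coefficients with intercept log(mean y) - mean
  offset; step-halving guards the rare deviance increase.
* Aliased (numerically collinear) design columns are detected by
  pivoted QR on norm-scaled columns and dropped with a warning —
  e.g. the above-threshold hinge when t exceeds every observed
  exposure, or year dummies against a coarse time spline.
* Threshold grid ties break to the smaller t; lag-selection ties break
  to the lexicographically smaller lag set.
* Moving-average windows that would reach before the start of a series
  are missing (rows dropped by complete-case filtering), so the default
  lag0-1 analysis drops the first day.
* Complete-case filtering is applied per fitted model to the exact set
  of required columns; missing values are never imputed.
* A spline basis needs at least df + 1 distinct values; violations
  raise immediately rather than producing a rank-deficient basis.

## Known limitations

* Plain Poisson likelihood: no overdispersion scaling. Real mortality
  series are often mildly overdispersed; deviance tests there are
  slightly anti-conservative.
* The bootstrap resamples days independently, ignoring serial
  dependence, and the threshold CI inherits the known irregularity of
  argmin estimators (percentile intervals can over-cover under strong
  signal and are not guaranteed to contain the point estimate).
* The pooled model shares one time trend across cities; city-specific
  trends are out of scope.
* Fixed-df bases mean absolute AICs differ from penalised-smoother
  implementations; only differences and signs are interpreted.
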