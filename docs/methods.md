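# Methods

`ssrlag` analyses how ambient temperature around the time of conception
relates to the secondary sex ratio (SSR) — the ratio of boys to girls at
birth — in monthly aggregated historical birth registers. This note records
the statistical model, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Data model

The unit of analysis is a birth month. For month *i* with `total_i` births of
which `girls_i` are girls,

    girls_i ~ Binomial(total_i, p_i),        logit p_i = eta_i.

The conception date of a birth month is estimated as the 15th of that month
minus 280 days of gestation (true, leap-aware calendar arithmetic). Because a
9-calendar-month span from the 15th is always 273–276 days, the conception
month is deterministically 9 calendar months before the birth month; the
day-level formula is kept because it is the defined estimator, not an
approximation of "9 months". Lag *k* ∈ {−9..+9} denotes the calendar month
*k* months after (*k* > 0) or before (*k* < 0) the conception month; lag +9
is the birth month itself. Rows whose 19-month lag window or conception-year
annual mean extends before the start of the temperature record are dropped
listwise (no imputation — the edges of the series are the only rows
affected), and the dropped count is reported.

## Model ladder

* **M0**: `eta = b0 + f_year(birth year) + f_month(birth month)` — a fully
  nonparametric trend and seasonal decomposition.
* **MT0**: M0 + `f_temp(T_year)`, where `T_year` is the mean annual
  temperature of the conception calendar year (the birth year is selectable;
  the two conventions disagree in the source material, so neither is
  guessed as the single intent — conception year is the default).
* **MTA**: M0 + an Almon polynomial distributed-lag block of the 19 monthly
  temperatures around conception.

### Penalized-spline smooths

`f_year` and `f_temp` use natural cubic regression splines with knots at
quantiles of the observed covariate (defaults: k = 10 basis functions for
year and temperature). `f_month` uses a cyclic cubic spline with period 12
(default k = 8), so the December–January transition is smooth. Both penalty
matrices are the exact integrated squared second derivative of the
interpolating spline; the cr penalty's null space is the linear functions,
the cyclic penalty's the constants.

Every smooth additionally carries a *null-space shrinkage penalty* (the
projection onto the roughness penalty's null space) with its own smoothing
parameter, so a term's effective degrees of freedom (edf) can reach 0 — an
absent seasonal effect really is reported as edf ≈ 0 rather than being
floored at its null-space dimension. Each smooth is centred to sum to zero
over the observed covariate values (constraint absorbed by a QR
reparameterisation); the intercept carries the overall level.

### Fitting and smoothness selection

Coefficients are estimated by penalized iteratively reweighted least squares
(PIRLS) on the grouped binomial likelihood, iterated to a relative penalized
-deviance change below 1e−8 (cap 200 iterations, with step halving).
Smoothing parameters minimise a Laplace-approximate REML criterion

    (D + b'Sb)/2 + log|X'WX + S|/2 − log|S|_+ /2

on the log-lambda scale (GCV is available as an alternative), by Nelder–Mead
from the best of three starts (log λ = −3, 0, +3 on all penalties) followed
by a tighter polish restart; log λ is clipped to ±18. The Bayesian
coefficient covariance `(X'WX + S)^{-1}` backs all intervals; per-term edf is
the trace of the term's block of `(X'WX + S)^{-1} X'WX`.

### Smooth-term tests

A smooth is tested against zero with the Wald quadratic form of its
coefficients against the Bayesian covariance, referred to a chi-square whose
degrees of freedom equal the term's edf floored at one. Simulation (in the
test suite) shows near-nominal size (~5–8% at α = 0.05) for terms whose
penalty retains an unpenalized direction after centring (year, temperature:
the linear part). For the cyclic month term the centring removes the whole
penalty null space, the term is fully penalized, and the test is
*conservative* under the null — the familiar behaviour of
penalization-aware tests for shrinkage smooths. Its p-values are reported
and usable as evidence against the null, not as calibrated error rates.

### Almon distributed lag

The 19 lag coefficients are constrained to a polynomial of degree *d* in the
lag index: `beta = T theta`, where T's columns are QR-orthonormalized powers
of the centred lag index. The reduced design `(lag matrix)·T` enters the GAM
as *d*+1 unpenalized parametric columns; `theta-hat` and its covariance are
mapped back by the delta method (`Cov(beta) = T Cov(theta) T'`) to per-lag
estimates, SEs and pointwise 95% intervals. The source analysis does not
state its degree; the default is **d = 3** (the single-trough lag profiles
seen in this literature are cubic-representable), configurable 1..6 with an
AIC scan (`almon_degree_scan`). No endpoint ("tail to zero") constraints are
imposed — published edge estimates are visibly nonzero. At d = L−1 = 18 the
constrained fit provably equals the unconstrained 19-column fit, which the
tests verify to 1e−6 in deviance.

Identification note: the seasonal-mean component of the lag temperatures is
a pure function of birth month and therefore collinear with `f_month`; with
shrinkage smooths REML resolves this in favour of the unpenalized lag block,
so the lag coefficients are identified chiefly by interannual temperature
anomalies. This mirrors the real analysis, where monthly temperature
*departures* from climatology carry the information.

## Climate characterization

Annual means use complete calendar years only. The decadal trend is the OLS
slope of annual mean on year (×10), with the standard two-sided t-test at
α = 0.05. Thermal classification: thresholds at the 5, 10, 20, 30, 40, 60,
70, 80, 90, 95th percentiles of the reference period — linear interpolation
between order statistics (the common default of mainstream statistical
environments; the choice is not pinned by the source, and counts near band
edges can shift by ±1 year under a different estimator). The 10 thresholds
define 11 ordered classes per scope (each calendar month separately, plus
annual means). Intervals are upper-closed: a value equal to a threshold
joins the band below. With tied thresholds the middle of the collapsed bands
is assigned — `(#thresholds < v + #thresholds ≤ v) // 2` — so an
all-constant series deterministically lands in the central "normal"
(40–60%) class. Class labels run "extremely cold" … "normal" … "extremely
warm" and are cosmetic; tests assert band indices.

## Synthetic-data generator

`simulate_temperature` draws monthly values as climatological mean + linear
trend (centred mid-period, so the monthly means stay period means) +
Gaussian noise with month-specific sd. Noise is independent by default, per
the design that the fitted models treat temperature as exogenous; the
Poznań-calibrated profile (`poznan_like_profile`) sets the optional AR(1)
knob to 0.4 because the published monthly sds (1.2–3.0 °C) and annual-mean
sd (0.8 °C) are mutually inconsistent under independence (which implies
≈0.57 °C) — month-to-month correlation of 0.4 reproduces both. Published
anchors: January −3.0, February/December −1.6, July 18.1 °C, annual mean
≈7.5 °C, trend 0.1 °C/decade; unpublished months are plausible mid-European
values chosen once so the annual mean is ≈7.5 °C.

`simulate_birth_series` draws monthly girl counts from the binomial with
`logit p = baseline + trend(birth year) + season[birth month] + Σ_l
beta_l · T(conception month + l)`. The default scenario uses baseline logit
−0.0556 (the pooled girl proportion of the historical register), no extra
trend or season, ~100 births/month over 1848–1900 (618 usable months after
lag trimming — the scale of the historical dataset), and a cubic
ground-truth lag profile through (−9, +0.0010), (−4, −0.0045), (0, −0.0020),
(+9, +0.0065) logit/°C — the ±0.005 order of magnitude of the published lag
estimates, exactly representable by the default d = 3 constraint so that
interval-coverage checks are meaningful. All randomness flows through
explicit integer seeds; there is no global random state.

**What passing synthetic tests do not show:** the generator has no
overdispersion relative to the binomial, no registration gaps or digit
preference, no gestational-age variation (every pregnancy is exactly 280
days), and temperature noise is Gaussian. Real-data conclusions inherit the
usual caveats of aggregated historical registers; the pipeline reproduces
the published analysis structure, it does not validate those data.

## Problem sizes used

Replicated checks run at the study scale (≈618 months × 100 births/month):
200 replicates for CI coverage, 150 for smooth-test null calibration, 100
for lag-flag calibration and for the acceptance script's coverage summary;
profile-correlation checks use 1 000 births/month. These sizes give
Monte-Carlo standard errors a few times smaller than the tolerances they
feed.

## Known limitations

* REML here is the Laplace/performance-iteration approximation (weights held
  at the PIRLS solution per criterion evaluation), not the fully nested
  optimization of the reference R implementation; selected λ can differ
  slightly, and printed edf/p of the original analysis are reproducible only
  approximately (basis dimensions and selection criterion were unreported).
* Smooth p-values for fully penalized (cyclic shrinkage) terms are
  conservative; see above.
* The Almon degree is a modelling choice; degree misspecification biases the
  lag profile toward its best polynomial approximation (the AIC scan is the
  guard).
* No simultaneous inference across lags: intervals are pointwise, as in the
  source tables.
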