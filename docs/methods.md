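# Methods

## Scope and model

`bchm` implements a daily-count environmental epidemiology chain: thermal
comfort indices from surface weather, exposure-lag screening, log-linear
Poisson regression with calendar adjustment, relative-risk/admission-
increase conversion, and holdout forecasting. The admission model for one
disease group is

    log E[Y_t] = alpha + sum_c beta_c * x_c(t - l_c) + calendar terms,
    Y_t ~ Poisson

with exposures x_c in their native units (ug/m3; ppm for CO; degC for the
comfort indices) and lags l_c in days. The error in the admission series
is interpreted as Poisson sampling variability around the log-linear
mean, not as an additive disturbance on the log scale; an optional
log-normal overdispersion term (`overdispersion_sd`, default 0) is
available in the generator for sensitivity work but is off everywhere.

## Thermal comfort indices

`ET(T, RH) = T - 0.4*(1 - RH/100)*(T - 10)` and the wind-adjusted
`ETw(T, RH, v)`. Two typographic variants of ETw circulate, differing in
whether the humidity-wind bracket divides or multiplies `(37 - T)`; the
division form matches the wind-chill literature's structure (more wind →
larger denominator contribution → stronger cooling below 37 degC) and is
the default, with the multiplicative form available as
`form="as_printed"`. Both share the T=37, RH=100 fixed point and both are
tested; which variant the original study computed cannot be determined
from its description, which is why both ship.

The five daily pairings label thermal regimes: (t_max, rh_min) hot-dry,
(t_max, rh_max) hot-wet, (t_mean, rh_mean) mean, (t_min, rh_max)
cold-wet, (t_min, rh_min) cold-dry. The assignment of "cold and wet" to
(minimum temperature, maximum humidity) follows the documented fact that
the variant-4 index is computed from minimum temperatures; it is the
index most sensitive to cold-front passages and the one associated with
admissions in all three disease groups. Temperatures are accepted in
degC only; no unit autodetection is attempted.

## Lag screening

Lags 0-7 are screened even though the synoptic-lag idea is often phrased
as "one to seven days": same-day (lag 0) associations are part of the
published lag tables and are biologically plausible for irritant
pollutants. Pearson r with the Student-t two-sided p-value (scipy's
implementation) is computed per lag on pairwise complete cases; the
selected lag maximizes |r| among lags significant at alpha (default
0.05), ties breaking toward the smaller lag (the more immediate effect).
A covariate with no significant lag is still reported at its max-|r| lag,
flagged non-significant.

Note a deliberate distinction in the validation suite: the per-lag test
is calibrated (~5% type-I at alpha=0.05), but the eight-lag scan is a
multiple test, so a pure-noise covariate escapes *all* lags only ~0.95^8
~ 66% of the time. The suite asserts both numbers rather than pretending
the scan itself has a 5% false-positive rate.

Screening runs on raw series by default. Shared seasonality inflates the
correlation level at every lag; an optional `detrend` flag removes a
centred 29-day moving average first. Lag *selection* is driven by the
synoptic (day-to-day) variation either way, which is why the default
matches standard practice of correlating raw series.

## Poisson fitting

IRLS/Fisher scoring with the log link, written from scratch:
`(X'WX) b = X'W z`, `W = diag(mu)`, `z = eta + (y - mu)/mu`, initialised
at `mu = (y + ybar)/2`. Convergence when the relative deviance change
drops below `tol` (default 1e-8); step-halving enforces a non-increasing
deviance after the first step (the first step leaves the heuristic
initialisation, whose deviance is not comparable, so only an overflow
guard applies there). Standard errors are `sqrt(diag((X'WX)^-1))` at the
optimum. The fitter is cross-checked against statsmodels' GLM to six
significant figures on random small designs; statsmodels is used only as
that oracle, never as the implementation.

Design construction: explicit intercept; exposures named
`{covariate}_lag{k}`; day-of-week dummies (reference Monday), month
dummies (reference January), a holiday dummy (fixed-date Brazilian
national holidays), optionally a nonrespiratory-admissions covariate.
Season-of-year dummies are omitted as exactly collinear with months.
The "nonparametric seasonality" adjustment is realised as an optional
centred cubic B-spline basis on the day index (`trend_df`, default off):
no specific smoother is canonical here, and months already absorb most
seasonal signal. Rows with any missing value (including lag-introduced
gaps) are dropped; a near-collinear column pair (|r| >= 0.99) triggers a
warning naming the pair, matching the known PM10-SO2 behaviour.

Goodness of fit uses the standard Poisson deviance
`2*sum[y*ln(y/mu) - (y - mu)]` (0*ln 0 = 0) and Pearson chi-square. A
binomial-flavoured deviance with an undefined per-day denominator
sometimes appears in print for this model; it is not implementable for
unbounded counts and the Poisson form is used.

## Risk metrics

`RR = exp(beta*X)`, `AI% = (RR - 1)*100`, CI95 `exp(X*(beta +/- 1.96 se))`.
The exposure change X multiplies inside the CI exponent — otherwise the
interval would not be the interval of the RR being reported; the
coefficient-scale variant (no X) is available as `as_printed=True`.
Reported AI values are rounded to one decimal, halves away from zero,
matching published ledgers. Coefficients recovered from a printed AI cell
(`invert_increase`) are rounded to three decimals: that is the only
convention under which each published row is internally consistent (e.g.
13.9% at +10 ug/m3 and 182.9% at +80 both follow exactly from 0.013).
Published URI and IP ledgers imply coefficients that differ from the
printed model coefficients (0.013/0.043/-0.011 vs 0.009/0.023/-0.007 for
URI; -0.020 vs -0.001 for IP ETw4); the ledgers are the self-consistent
set and are treated as authoritative for risk reproduction, while the
printed model coefficients are retained in `bchm.published` as fitted
values.

## Forecasting and skill

Predictions are `P_i = exp(X_i . beta_hat)` on a holdout whose design
columns must match the training design by name. Skill is reported both
as MSE `(1/n) sum (P_i - O_i)^2` — in squared counts, which for a
correctly specified model converges to the mean daily variance, i.e. the
mean expected count — and as MAPE `(100/n) sum |P_i - O_i|/max(O_i, 1)`,
the percentage-scale figure (denominator floored at 1 to keep zero-count
days finite). MSE in squared counts cannot itself be a percentage, which
is why both are always reported side by side. The pipeline's holdout
convention trains on four years and scores a fifth generated year.

## Synthetic-data generator

The generator emulates a Sao Paulo-like record, not any deposited data:

- **Weather.** Daily mean temperature = 19.5 + 4.5*cos(2*pi*(doy - 26)/365.25)
  degC (annual mean and semi-amplitude of the subtropical Southeast;
  maximum late January, minimum late July) plus an AR(1) synoptic anomaly
  with coefficient 0.55 and innovation sd 2.5 degC (stationary sd ~3
  degC, a realistic synoptic scale; the AR scale also gives the lagged
  comfort signal its day-to-day identifiability). Min/max offsets keep
  t_min < t_mean < t_max by construction; relative humidity is linear in
  the temperature anomaly with negative slope plus noise (sample
  correlation ~ -0.9); wind ~2.2 m/s; pressure ~930 hPa (altitude ~800 m)
  with a weak winter maximum; precipitation is a summer-peaking
  zero-inflated exponential. All weather noise scales with `noise_sd`, so
  `noise_sd=0` returns the exact deterministic seasonal curves.
- **Pollution.** PM10 and SO2 load on one standardized winter-peaking
  latent factor (seasonal + AR(1)) so their population correlation equals
  `collinearity_rho` (default 0.8; the collinearity experiments use
  0.95); CO loads on the same factor more weakly; O3 has a spring
  (mid-October) seasonal peak; NO2 winter-leaning. Means and sds
  (PM10 48±20, SO2 14±7 ug/m3, CO 2.8±1.2 ppm, O3 62±28 ug/m3) are
  pegged at late-1990s urban Sao Paulo levels. Concentrations are
  truncated at a small positive floor.
- **Admissions.** Poisson draws from the log-linear mean with the
  configured coefficients, lags and calendar offsets (weekend deficits
  -0.15/-0.25, holidays -0.1 on the log scale — admissions drop when
  outpatient referral slows). The default truth is the LRI coefficient
  set (alpha 1.661; PM10 0.001 lag 0; O3 0.002 lag 3; ETw4 -0.012 lag 3),
  over 1461 days (four years), mirroring the study design the chain is
  validated against. The first max-lag days are emitted with missing
  counts and a `burn_in` flag rather than silently dropped.

Every stream is a deterministic function of `(config, seed)`; the dataset
carries a byte-identical echo of its configuration in `truth`.

What the generator does **not** emulate: synoptic weather dynamics beyond
AR(1), spatial structure across monitors, inversion episodes, epidemic
waves, day-of-week structure in exposures, or measurement error. Passing
recovery tests therefore demonstrate that the chain is correct under its
own assumptions — unbiased estimation, correct lag attribution, calibrated
intervals — not that real admission data meet those assumptions.

## Validation design and problem sizes

- Risk-table reproduction is exact desk arithmetic (64 ledger cells plus
  the headline summary percentages).
- GLM correctness: closed forms plus a 20-dataset statsmodels
  cross-check at 6 significant figures.
- Parameter recovery: 200 independent four-year scenarios; mean estimates
  within 2 Monte-Carlo standard errors of truth; ETw4's planted lag 3
  recovered by screening in >= 90% of runs. 200 replicates keep the
  Monte-Carlo SE of the recovery rate under 2.5 points while the whole
  experiment stays a few seconds of compute.
- Collinearity: 30 seeds at rho = 0.95; in a majority, a pollutant that
  is individually significant loses significance in the joint model.
- Forecast calibration: Poisson 95% prediction-interval coverage pooled
  over 5 scenarios; oracle-vs-fitted MSE ordering averaged over 30 seeds.

## Known limitations

- The empirical lag-correlation table, admission proportions, figure
  curves and real-data validation errors of the original record require
  the undeposited 1997-2001 monitoring data and are out of scope; the
  property suites above stand in for them.
- No quasi-Poisson/negative-binomial corrections, GAM smoothers, or
  autocorrelation-robust errors; the spline trend is a convenience, not a
  fitted-df smoother.
- Fixed-date holidays only (no movable feasts).
- The screening step inherits the multiplicity caveat above; its flags
  are descriptive, not family-wise error controlled.
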