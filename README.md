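# bchm — climate-and-health modelling of respiratory hospital admissions

`bchm` implements a daily time-series modelling chain for environmental
epidemiology: it predicts daily counts of respiratory hospital admissions
from air pollutants (PM₁₀, SO₂, NO₂, O₃ in µg/m³; CO in ppm), surface
meteorology and effective-temperature thermal comfort indices. The chain
mirrors the modelling used for São Paulo children's admissions (1997–2000),
where admissions were grouped as **URI** (upper respiratory infections,
ICD-10 J00–J06, J30–J39), **LRI** (lower respiratory infections and chronic
lower respiratory diseases, J20–J22, J40–J47) and **IP** (influenza and
pneumonia, J10–J18). It is written for epidemiologists and
biometeorologists who want a tested, reproducible version of each step,
with a synthetic-data generator carrying known ground truth so the whole
chain can be validated by parameter recovery.

## The model

1. **Thermal comfort indices.** Effective temperature combines temperature
   and humidity into a perceived temperature,

   `ET = T − 0.4·(1 − RH/100)·(T − 10)`,

   and the wind-adjusted variant adds a wind-chill-like term,

   `ETw = 37 − (37 − T)/(0.68 − 0.0014·RH + 1/(1.76 + 1.4·v^0.75)) − 0.29·T·(1 − RH/100)`.

   Ten daily variants pair the day's temperature and humidity extremes;
   variant 4 — minimum temperature with maximum humidity, "cold and wet" —
   is the index that tracks incoming cold fronts. The ETw formula also
   circulates in a typographic variant that multiplies rather than divides
   by the bracket; both are implemented (`form="division"` is the default).

2. **Lag screening.** Each covariate is shifted by 0–7 days (admissions on
   day *t* paired with exposure on day *t − k*) and Pearson-correlated with
   the admission series; the selected lag maximizes |r| among significant
   lags at α = 0.05.

3. **Poisson regression.** For each disease group,

   `log E[Y_t] = α + Σ_c β_c·x_c(t − ℓ_c) + calendar terms`,

   with dummy adjustment for day of week, month and holidays, fitted by a
   hand-written IRLS (Fisher scoring) loop with step-halving; deviance and
   Pearson χ² diagnostics; standard errors from the inverse Fisher
   information.

4. **Risk metrics.** A coefficient β and exposure change X give the
   relative risk `RR = exp(β·X)`, the percent admission increase
   `AI = (exp(β·X) − 1)·100`, and the 95% CI `exp(X·(β ± 1.96·se))`.
   `increase_table` lays AI out over an 8-step exposure grid, and
   `invert_increase` recovers β = ln(1 + AI/100)/X from a printed cell.

5. **Forecasting.** A fitted model predicts a holdout year; skill is
   reported as the mean squared error (1/n)·Σ(Pᵢ − Oᵢ)² and as MAPE,
   (100/n)·Σ|Pᵢ − Oᵢ|/max(Oᵢ, 1).

The synthetic generator produces Southern-hemisphere weather (annual cycle
peaking in late January plus AR(1) synoptic anomalies, humidity
anticorrelated with temperature), pollutants with a shared winter-peaking
factor (configurable PM₁₀–SO₂ collinearity) and spring-peaking ozone, and
Poisson admissions from the log-linear model with known coefficients and
lags.

## Worked example

Simulate four years with the LRI coefficient set (β_PM10 = 0.001 per µg/m³
at lag 0, β_O3 = 0.002 at lag 3, β_ETw4 = −0.012 per °C at lag 3,
α = 1.661), screen lags, fit, and tabulate risk:

```python
from bchm import (ScenarioConfig, generate_dataset, DesignSpec,
                  build_design, fit_irls, increase_table, screen)
from bchm.datagen import modelling_frame

cfg = ScenarioConfig(seed=2)              # four simulated years, LRI truth
frame = modelling_frame(generate_dataset(cfg))

usable = frame[~frame["burn_in"]].reset_index(drop=True)
for r in screen(usable["LRI"], usable[["pm10", "o3", "etw4"]]):
    print(f"{r.covariate}: best lag {r.best_lag}, r = {r.r:+.3f} (p = {r.p_value:.2g})")

spec = DesignSpec(exposure_terms=(("pm10", 0), ("o3", 3), ("etw4", 3)))
X, y = build_design(frame, spec, response="LRI")
fit = fit_irls(X, y)
for name in ("pm10_lag0", "o3_lag3", "etw4_lag3"):
    i = fit.columns.index(name)
    print(f"{name}: beta = {fit.beta[i]:+.5f} (se {fit.se[i]:.5f})")

i = fit.columns.index("pm10_lag0")
tbl = increase_table(fit.beta[i], unit_step=20.0, covariate="pm10", se=fit.se[i])
print("PM10 increases (%):", tbl.increase_pct)
```

prints

```
pm10: best lag 1, r = +0.079 (p = 0.0027)
o3: best lag 3, r = +0.172 (p = 4.4e-11)
etw4: best lag 3, r = -0.175 (p = 1.8e-11)
pm10_lag0: beta = +0.00027 (se 0.00067)
o3_lag3: beta = +0.00234 (se 0.00051)
etw4_lag3: beta = -0.01329 (se 0.00286)
PM10 increases (%): [0.5, 1.1, 1.6, 2.2, 2.7, 3.2, 3.8, 4.3]
```

The strong planted effects (O₃ and ETw4) are recovered — right lags, right
signs, estimates within a standard error or two of truth. PM₁₀'s planted
effect (0.001·20 µg/m³ ≈ 2% per step) is small relative to Poisson noise
in a single four-year sample, so its lag and coefficient are imprecise on
any one run; averaged over 200 simulations the estimates are unbiased (see
`tests/test_acceptance.py`). The increase table converts the fitted PM₁₀
coefficient into the percent extra admissions per 20 µg/m³ step.

The same chain is available from the shell:

```
bchm run --group LRI --seed 2 --out runs/lri
bchm simulate --seed 3 --out sim/        # or stage by stage
bchm comfort --in sim/weather.csv --out sim/indices.csv
```

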