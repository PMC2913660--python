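"""Synthetic daily environment and admission series with known truth.

The generator emulates the statistical structure of a subtropical
Southern-hemisphere urban monitoring record (Sao Paulo-like):

* weather — a sinusoidal annual cycle peaking in late January (minimum
  mid-year) plus AR(1) synoptic anomalies; relative humidity
  anticorrelated with temperature; daily min/mean/max ordered by
  construction;
* pollution — PM10 and SO2 driven by a shared winter-peaking latent
  factor with configurable correlation (both are primary/combustion
  pollutants trapped by winter inversions); CO winter-peaking; O3
  photochemical, peaking in spring; concentrations truncated at zero;
* admissions — Poisson counts from the log-linear model
  ``log mu_t = alpha + sum_c beta_c x_c(t - lag_c) + calendar offsets``
  with user-specified ground-truth coefficients and lags, so that
  screening and regression can be validated by parameter recovery.

Everything is a deterministic function of the scenario configuration,
including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .comfort import comfort_table
from .published import EXPOSURE_SETS, INTERCEPTS, MODEL_COEFFICIENTS

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "brazilian_holidays",
    "generate_weather",
    "generate_pollution",
    "generate_admissions",
    "generate_dataset",
    "scenario_for_group",
]

DAYS_PER_YEAR = 365.25
_TEMP_PEAK_DOY = 26.0    # late January: austral summer maximum
_WINTER_PEAK_DOY = 208.0  # late July: austral winter
_SPRING_PEAK_DOY = 288.0  # mid October: photochemical ozone season

#: fixed-date national holidays (month, day)
_HOLIDAYS = [(1, 1), (4, 21), (5, 1), (9, 7), (10, 12), (11, 2), (11, 15), (12, 25)]


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground truth for one synthetic scenario.

    Parameters
    ----------
    n_days : int
        Series length; default 1461 days (four years, the length of a
        typical multi-year admission study).
    seed : int
        Master seed; all streams derive from it.
    group : str
        Disease-group label attached to the admission series.
    baseline_log_rate : float
        Intercept alpha (log daily admissions at zero covariates).
    true_beta : dict
        Covariate -> log-scale coefficient per covariate unit.
    lags : dict
        Covariate -> exposure lag in days (0-7).
    dow_effects, month_effects : dict
        Additive log-scale calendar offsets keyed by lowercase day/month
        name; unlisted categories are 0 (Monday/January references).
    holiday_effect : float
        Additive log-scale offset on holidays.
    collinearity_rho : float
        Target PM10-SO2 correlation, in [0, 1).
    noise_sd : float
        Meteorology AR(1) innovation standard deviation (degC); all other
        weather noise scales proportionally, so 0 gives the deterministic
        seasonal curves.
    ar_coef : float
        AR(1) coefficient of the synoptic temperature anomaly.
    overdispersion_sd : float
        Optional log-normal extra-Poisson noise on the log mean
        (default 0: pure Poisson sampling variability).
    t_mean_annual, t_amplitude : float
        Annual mean and seasonal semi-amplitude of daily mean temperature.
    """

    n_days: int = 1461
    seed: int = 0
    group: str = "LRI"
    baseline_log_rate: float = INTERCEPTS["LRI"]
    true_beta: dict = field(
        default_factory=lambda: dict(MODEL_COEFFICIENTS["LRI"])
    )
    lags: dict = field(
        default_factory=lambda: dict(EXPOSURE_SETS["LRI"])
    )
    dow_effects: dict = field(
        default_factory=lambda: {"sat": -0.15, "sun": -0.25}
    )
    month_effects: dict = field(default_factory=dict)
    holiday_effect: float = -0.1
    collinearity_rho: float = 0.8
    noise_sd: float = 2.5
    ar_coef: float = 0.55
    overdispersion_sd: float = 0.0
    t_mean_annual: float = 19.5
    t_amplitude: float = 4.5
    start_date: str = "1997-01-01"

    def __post_init__(self) -> None:
        max_lag = max(self.lags.values(), default=0)
        if self.n_days < 30 + max_lag:
            raise ValueError(f"n_days must be >= {30 + max_lag}")
        for cov, lag in self.lags.items():
            if not 0 <= lag <= 7:
                raise ValueError(f"lag {lag} for {cov} outside [0, 7]")
        if not 0 <= self.collinearity_rho < 1:
            raise ValueError("collinearity_rho must be in [0, 1)")
        if self.noise_sd < 0 or self.overdispersion_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must be in [0, 1)")
        extra = set(self.true_beta) - set(self.lags)
        if extra:
            raise ValueError(f"true_beta covariates without a lag: {sorted(extra)}")

    @property
    def max_lag(self) -> int:
        return max(self.lags.values(), default=0)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


@dataclass
class SyntheticDataset:
    """Bundle of generated series plus the ground-truth configuration."""

    weather: pd.DataFrame
    pollution: pd.DataFrame
    comfort: pd.DataFrame
    admissions: pd.DataFrame
    truth: ScenarioConfig


def scenario_for_group(group: str, **overrides) -> ScenarioConfig:
    """Scenario whose truth is a published disease-group coefficient set."""
    if group not in EXPOSURE_SETS:
        raise ValueError(f"unknown disease group {group!r}")
    cfg = ScenarioConfig(
        group=group,
        baseline_log_rate=INTERCEPTS[group],
        true_beta=dict(MODEL_COEFFICIENTS[group]),
        lags=dict(EXPOSURE_SETS[group]),
    )
    return replace(cfg, **overrides) if overrides else cfg


def brazilian_holidays(dates: pd.DatetimeIndex) -> np.ndarray:
    """0/1 flag for fixed-date national holidays."""
    md = list(zip(dates.month, dates.day))
    return np.array([1 if x in _HOLIDAYS else 0 for x in md], dtype=int)


def _seasonal(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (doy - peak_doy) / DAYS_PER_YEAR)


def _ar1(rng: np.random.Generator, n: int, phi: float, innov_sd: float) -> np.ndarray:
    if innov_sd == 0:
        return np.zeros(n)
    e = rng.normal(0.0, innov_sd, size=n)
    out = np.empty(n)
    # start from the stationary distribution
    out[0] = e[0] / np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + e[t]
    return out


def _rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def generate_weather(cfg: ScenarioConfig) -> pd.DataFrame:
    """Daily weather table with Southern-hemisphere seasonality.

    With ``noise_sd=0`` every column equals its deterministic seasonal
    curve (temperatures, humidity, wind, pressure, precipitation all lose
    their stochastic parts).
    """
    rng = _rng(cfg, 1)
    dates = cfg.dates()
    doy = dates.dayofyear.to_numpy(dtype=float)
    n = cfg.n_days
    scale = cfg.noise_sd / 2.5  # proportional noise for the non-AR fields

    seasonal_t = cfg.t_mean_annual + cfg.t_amplitude * _seasonal(doy, _TEMP_PEAK_DOY)
    anomaly = _ar1(rng, n, cfg.ar_coef, cfg.noise_sd)
    t_mean = seasonal_t + anomaly
    half_up = 4.0 + np.abs(rng.normal(0.0, 1.0, n)) * 0.75 * scale
    half_dn = 4.0 + np.abs(rng.normal(0.0, 1.0, n)) * 0.75 * scale
    t_max = t_mean + half_up
    t_min = t_mean - half_dn

    # humidity anticorrelated with the temperature anomaly + its own noise
    rh_mean = 75.0 - 1.5 * (t_mean - cfg.t_mean_annual) + rng.normal(0, 3.0 * scale, n)
    rh_mean = np.clip(rh_mean, 20.0, 100.0)
    rh_max = np.clip(rh_mean + 15.0 + np.abs(rng.normal(0, 2.0 * scale, n)), None, 100.0)
    rh_min = np.clip(rh_mean - 18.0 - np.abs(rng.normal(0, 2.0 * scale, n)), 5.0, None)

    wind = np.clip(2.2 + rng.normal(0, 0.6 * scale, n), 0.1, None)
    pressure = 930.0 + 2.0 * _seasonal(doy, _WINTER_PEAK_DOY) + rng.normal(0, 1.5 * scale, n)

    precip_mean = 6.0 + 5.0 * _seasonal(doy, _TEMP_PEAK_DOY)  # wet summers
    if cfg.noise_sd == 0:
        precip = precip_mean
    else:
        p_wet = np.clip(precip_mean / 12.0, 0.05, 0.9)
        wet = rng.random(n) < p_wet
        precip = np.where(wet, rng.exponential(1.0, n) * precip_mean / p_wet, 0.0)

    return pd.DataFrame(
        {
            "date": dates,
            "t_mean": t_mean,
            "t_min": t_min,
            "t_max": t_max,
            "rh_mean": rh_mean,
            "rh_min": rh_min,
            "rh_max": rh_max,
            "wind_mean": wind,
            "pressure": pressure,
            "precipitation": precip,
        }
    )


#: pollutant climatology: mean, sd, winter-factor loading, unit
_POLLUTANTS = {
    "pm10": (48.0, 20.0, "ug/m3"),
    "so2": (14.0, 7.0, "ug/m3"),
    "co": (2.8, 1.2, "ppm"),
    "no2": (58.0, 22.0, "ug/m3"),
    "o3": (62.0, 28.0, "ug/m3"),
}


def generate_pollution(cfg: ScenarioConfig, weather: pd.DataFrame) -> pd.DataFrame:
    """Daily pollutant concentrations tied to the weather calendar.

    PM10 and SO2 load on one standardized winter-peaking latent factor so
    their population correlation equals ``collinearity_rho``; CO shares
    the winter factor more weakly; O3 follows a spring-peaking cycle.
    All series are truncated below at a small positive floor.
    """
    rng = _rng(cfg, 2)
    dates = pd.to_datetime(weather["date"])
    doy = dates.dt.dayofyear.to_numpy(dtype=float)
    n = len(weather)

    # standardized winter factor: seasonal + AR(1), unit population variance
    seas = _seasonal(doy, _WINTER_PEAK_DOY)
    ar = _ar1(rng, n, 0.6, 1.0)
    z = (1.1 * seas + ar) / np.sqrt(1.1**2 * 0.5 + 1.0 / (1.0 - 0.6**2))

    rho = cfg.collinearity_rho
    lo, res = np.sqrt(rho), np.sqrt(1.0 - rho)
    u = rng.normal(0.0, 1.0, size=(4, n))

    out = {"date": dates.to_numpy()}
    m, s, _ = _POLLUTANTS["pm10"]
    out["pm10"] = m + s * (lo * z + res * u[0])
    m, s, _ = _POLLUTANTS["so2"]
    out["so2"] = m + s * (lo * z + res * u[1])
    m, s, _ = _POLLUTANTS["co"]
    out["co"] = m + s * (0.6 * z + 0.8 * u[2])
    m, s, _ = _POLLUTANTS["no2"]
    out["no2"] = m + s * (0.5 * z + 0.87 * rng.normal(0, 1, n))
    m, s, _ = _POLLUTANTS["o3"]
    out["o3"] = m + 20.0 * _seasonal(doy, _SPRING_PEAK_DOY) + s * 0.8 * u[3]

    df = pd.DataFrame(out)
    for col in _POLLUTANTS:
        df[col] = np.clip(df[col], 0.5 if col != "co" else 0.05, None)
    return df


def generate_admissions(
    cfg: ScenarioConfig,
    pollution: pd.DataFrame,
    comfort: pd.DataFrame,
) -> pd.DataFrame:
    """Poisson daily admission counts from the log-linear truth.

    Day t's log mean adds each configured coefficient times its covariate
    at day ``t - lag`` plus calendar offsets.  The first ``max_lag`` days
    cannot be evaluated and are emitted with a missing count and
    ``burn_in=True``.

    Raises
    ------
    OverflowError
        If a log mean exceeds a safe bound; the message names the
        covariate contributing the largest term.
    """
    rng = _rng(cfg, 3)
    dates = cfg.dates()
    n = cfg.n_days
    cov = pollution.drop(columns=["date"], errors="ignore").copy()
    comfort_cols = comfort.drop(columns=["date"], errors="ignore")
    for c in comfort_cols.columns:
        cov[c] = comfort_cols[c].to_numpy()
    for c in cfg.true_beta:
        if c not in cov.columns:
            raise ValueError(f"truth covariate {c!r} not found in generated series")

    log_mu = np.full(n, cfg.baseline_log_rate)
    contrib = {}
    for c, beta in cfg.true_beta.items():
        lag = cfg.lags[c]
        x = cov[c].to_numpy(dtype=float)
        shifted = np.full(n, np.nan)
        shifted[lag:] = x[: n - lag] if lag else x
        term = beta * shifted
        contrib[c] = term
        log_mu = log_mu + np.where(np.isnan(term), 0.0, term)

    dow = dates.dayofweek.to_numpy()
    dow_names = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]
    for d, name in enumerate(dow_names):
        off = cfg.dow_effects.get(name, 0.0)
        if off:
            log_mu = log_mu + off * (dow == d)
    month_names = ["jan", "feb", "mar", "apr", "may", "jun", "jul", "aug",
                   "sep", "oct", "nov", "dec"]
    months = dates.month.to_numpy()
    for m, name in enumerate(month_names, start=1):
        off = cfg.month_effects.get(name, 0.0)
        if off:
            log_mu = log_mu + off * (months == m)
    holiday = brazilian_holidays(dates)
    log_mu = log_mu + cfg.holiday_effect * holiday

    burn_in = np.arange(n) < cfg.max_lag
    valid = ~burn_in
    if np.any(log_mu[valid] > 35.0):
        t_bad = int(np.argmax(np.where(valid, log_mu, -np.inf)))
        worst = max(contrib, key=lambda c: abs(np.nan_to_num(contrib[c][t_bad])))
        raise OverflowError(
            f"log admission mean {log_mu[t_bad]:.1f} on day {t_bad} overflows; "
            f"largest contribution from coefficient on {worst!r}"
        )
    if cfg.overdispersion_sd > 0:
        log_mu = log_mu + rng.normal(0.0, cfg.overdispersion_sd, n)

    counts = np.full(n, np.nan)
    counts[valid] = rng.poisson(np.exp(log_mu[valid])).astype(float)
    return pd.DataFrame(
        {
            "date": dates,
            cfg.group: counts,
            "burn_in": burn_in,
            "holiday": holiday,
        }
    )


def generate_dataset(cfg: ScenarioConfig, etw_form: str = "division") -> SyntheticDataset:
    """Full scenario: weather -> comfort -> pollution -> admissions.

    The returned ``truth`` field echoes the input configuration unchanged.
    """
    weather = generate_weather(cfg)
    comfort = comfort_table(weather, etw_form=etw_form)
    pollution = generate_pollution(cfg, weather)
    admissions = generate_admissions(cfg, pollution, comfort)
    return SyntheticDataset(
        weather=weather,
        pollution=pollution,
        comfort=comfort,
        admissions=admissions,
        truth=cfg,
    )


def modelling_frame(ds: SyntheticDataset) -> pd.DataFrame:
    """Single tidy daily table: covariates + count + calendar flags."""
    df = ds.pollution.merge(ds.comfort, on="date").merge(ds.admissions, on="date")
    return df


def config_to_dict(cfg: ScenarioConfig) -> dict:
    return asdict(cfg)
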