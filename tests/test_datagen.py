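"""Synthetic-scenario generator: determinism, seasonality, planted truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bchm.datagen import (
    DAYS_PER_YEAR,
    ScenarioConfig,
    brazilian_holidays,
    generate_admissions,
    generate_dataset,
    generate_pollution,
    generate_weather,
    scenario_for_group,
)


def test_config_validation():
    with pytest.raises(ValueError, match="n_days"):
        ScenarioConfig(n_days=10)
    with pytest.raises(ValueError, match="lag"):
        ScenarioConfig(true_beta={"pm10": 0.0}, lags={"pm10": 9})
    with pytest.raises(ValueError, match="collinearity_rho"):
        ScenarioConfig(collinearity_rho=1.0)
    with pytest.raises(ValueError, match="without a lag"):
        ScenarioConfig(true_beta={"pm10": 0.0, "xyz": 1.0}, lags={"pm10": 0})


def test_zero_noise_weather_is_deterministic_seasonal_curve():
    cfg = ScenarioConfig(noise_sd=0.0, n_days=730)
    w = generate_weather(cfg)
    doy = w["date"].dt.dayofyear.to_numpy(dtype=float)
    seasonal = cfg.t_mean_annual + cfg.t_amplitude * np.cos(
        2 * np.pi * (doy - 26.0) / DAYS_PER_YEAR
    )
    np.testing.assert_allclose(w["t_mean"], seasonal, atol=1e-12)
    # every stochastic weather component collapses
    assert w["wind_mean"].nunique() == 1
    np.testing.assert_allclose(w["t_max"] - w["t_mean"], 4.0)


def test_southern_hemisphere_phase():
    w = generate_weather(ScenarioConfig(noise_sd=0.0))
    monthly = w.groupby(w["date"].dt.month)["t_mean"].mean()
    assert monthly.idxmin() == 7   # coldest mid-year (austral winter)
    assert monthly.idxmax() == 1   # warmest in January


def test_weather_determinism_and_ordering(default_dataset):
    cfg = default_dataset.truth
    again = generate_weather(cfg)
    pd.testing.assert_frame_equal(default_dataset.weather, again)
    w = default_dataset.weather
    assert (w["t_min"] < w["t_mean"]).all() and (w["t_mean"] < w["t_max"]).all()
    assert w["rh_mean"].between(0, 100).all()
    assert (w["rh_min"] <= w["rh_mean"]).all() and (w["rh_mean"] <= w["rh_max"]).all()


def test_weather_mean_recovery_monte_carlo(default_dataset):
    """Sample mean of t_mean within 0.5 degC of the configured annual mean."""
    w = default_dataset.weather
    assert abs(w["t_mean"].mean() - default_dataset.truth.t_mean_annual) < 0.5


def test_humidity_anticorrelated_with_temperature(default_dataset):
    w = default_dataset.weather
    assert np.corrcoef(w["t_mean"], w["rh_mean"])[0, 1] < -0.5


@pytest.mark.parametrize("rho", [0.0, 0.8])
def test_pm10_so2_collinearity_dial(rho, default_dataset):
    cfg = dataclasses.replace(default_dataset.truth, collinearity_rho=rho)
    pol = generate_pollution(cfg, default_dataset.weather)
    got = np.corrcoef(pol["pm10"], pol["so2"])[0, 1]
    assert got == pytest.approx(rho, abs=0.1)
    assert (pol[["pm10", "so2", "co", "no2", "o3"]] > 0).all().all()


def test_ozone_peaks_in_spring(default_dataset):
    pol = default_dataset.pollution
    month = pd.to_datetime(pol["date"]).dt.month
    spring = pol.loc[month.isin([9, 10, 11]), "o3"].mean()
    autumn = pol.loc[month.isin([3, 4, 5]), "o3"].mean()
    winter_pm = pol.loc[month.isin([6, 7, 8]), "pm10"].mean()
    summer_pm = pol.loc[month.isin([12, 1, 2]), "pm10"].mean()
    assert spring > autumn
    assert winter_pm > summer_pm


def test_intercept_only_admissions_are_poisson(default_dataset):
    cfg = dataclasses.replace(
        default_dataset.truth,
        true_beta={}, lags={}, baseline_log_rate=np.log(5.0),
        dow_effects={}, month_effects={}, holiday_effect=0.0,
    )
    adm = generate_admissions(cfg, default_dataset.pollution, default_dataset.comfort)
    counts = adm[cfg.group].dropna()
    # mean 5, var 5: three-sigma Monte-Carlo bands at n=1461
    assert counts.mean() == pytest.approx(5.0, abs=3 * np.sqrt(5 / len(counts)))
    assert counts.var() == pytest.approx(5.0, rel=0.15)
    assert (counts >= 0).all() and (counts == counts.round()).all()


def test_paired_shift_matches_closed_form(default_dataset):
    """Shifting PM10 by +160 with beta 0.001 scales means by exp(0.16)."""
    cfg = dataclasses.replace(
        default_dataset.truth,
        true_beta={"pm10": 0.001}, lags={"pm10": 0},
        dow_effects={}, month_effects={}, holiday_effect=0.0,
    )
    base = generate_admissions(cfg, default_dataset.pollution, default_dataset.comfort)
    shifted_pol = default_dataset.pollution.copy()
    shifted_pol["pm10"] = shifted_pol["pm10"] + 160.0
    shifted = generate_admissions(cfg, shifted_pol, default_dataset.comfort)
    ratio = shifted[cfg.group].mean() / base[cfg.group].mean()
    assert ratio == pytest.approx(np.exp(0.16), rel=0.03)


def test_burn_in_flagging(default_dataset):
    adm = default_dataset.admissions
    max_lag = default_dataset.truth.max_lag
    assert adm["burn_in"].iloc[:max_lag].all()
    assert not adm["burn_in"].iloc[max_lag:].any()
    assert adm.loc[adm["burn_in"], "LRI"].isna().all()
    assert adm.loc[~adm["burn_in"], "LRI"].notna().all()


def test_overflow_names_offending_coefficient(default_dataset):
    cfg = dataclasses.replace(
        default_dataset.truth, true_beta={"pm10": 5.0}, lags={"pm10": 0}
    )
    with pytest.raises(OverflowError, match="pm10"):
        generate_admissions(cfg, default_dataset.pollution, default_dataset.comfort)


def test_dataset_truth_echo_and_determinism(default_dataset):
    cfg = default_dataset.truth
    assert cfg == ScenarioConfig(seed=0)  # byte-identical echo of the input
    again = generate_dataset(cfg)
    pd.testing.assert_frame_equal(default_dataset.admissions, again.admissions)
    pd.testing.assert_frame_equal(default_dataset.pollution, again.pollution)


def test_series_lengths_align(default_dataset):
    n = default_dataset.truth.n_days
    for df in (default_dataset.weather, default_dataset.pollution,
               default_dataset.comfort, default_dataset.admissions):
        assert len(df) == n


def test_scenario_for_group_uses_published_sets():
    cfg = scenario_for_group("URI")
    assert cfg.lags == {"so2": 0, "co": 0, "etw4": 4}
    assert cfg.true_beta["co"] == 0.023
    with pytest.raises(ValueError, match="unknown disease group"):
        scenario_for_group("XXX")


def test_holiday_flag():
    dates = pd.date_range("1997-12-24", periods=3)
    assert list(brazilian_holidays(dates)) == [0, 1, 0]


def test_overdispersion_knob_increases_variance(default_dataset):
    cfg = dataclasses.replace(
        default_dataset.truth,
        true_beta={}, lags={}, baseline_log_rate=np.log(8.0),
        dow_effects={}, month_effects={}, holiday_effect=0.0,
    )
    plain = generate_admissions(cfg, default_dataset.pollution, default_dataset.comfort)
    noisy_cfg = dataclasses.replace(cfg, overdispersion_sd=0.5)
    noisy = generate_admissions(noisy_cfg, default_dataset.pollution,
                                default_dataset.comfort)
    assert noisy[cfg.group].var() > 1.5 * plain[cfg.group].var()
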