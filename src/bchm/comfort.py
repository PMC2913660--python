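"""Effective-temperature thermal comfort indices.

Two perceived-temperature scales are implemented:

* the effective temperature ``ET(T, RH)``, which discounts the air
  temperature for dryness below saturation,

  .. math:: ET = T - 0.4\\,(1 - RH/100)\\,(T - 10)

* the wind-adjusted effective temperature ``ETw(T, RH, v)``, which adds a
  wind-chill-like correction driven by the mean wind speed ``v``.

Both take air temperature in degrees Celsius, relative humidity in percent
and (for ETw) wind speed in m/s.  Ten daily index variants are derived by
pairing the day's temperature and humidity extremes:

====== ================== =====================
 k      pairing            thermal regime
====== ================== =====================
 1      (t_max, rh_min)    hot and dry
 2      (t_max, rh_max)    hot and wet
 3      (t_mean, rh_mean)  mean conditions
 4      (t_min, rh_max)    cold and wet
 5      (t_min, rh_min)    cold and dry
====== ================== =====================

``et{k}`` applies ET to the pairing; ``etw{k}`` applies ETw to the same
pairing together with the day's mean wind.  Variant 4 (minimum temperature
with maximum humidity) is the "cold and wet" index that tracks incoming
cold fronts and is the comfort covariate most strongly associated with
respiratory admissions.

The wind formula circulates in two typographic variants that differ in
whether the bracketed wind term divides or multiplies ``(37 - T)``; the
division form is the default and the multiplicative one is available as
``form="as_printed"``.  Both agree at the fixed point T=37, RH=100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DailyWeather",
    "ComfortIndices",
    "PAIRINGS",
    "effective_temperature",
    "effective_temperature_wind",
    "comfort_suite",
    "comfort_table",
    "ThermalComfortTransformer",
]

EtwForm = Literal["division", "as_printed"]

#: temperature/humidity column pairing for each index variant
PAIRINGS: dict[int, tuple[str, str]] = {
    1: ("t_max", "rh_min"),
    2: ("t_max", "rh_max"),
    3: ("t_mean", "rh_mean"),
    4: ("t_min", "rh_max"),
    5: ("t_min", "rh_min"),
}

WEATHER_COLUMNS = [
    "t_mean",
    "t_min",
    "t_max",
    "rh_mean",
    "rh_min",
    "rh_max",
    "wind_mean",
    "pressure",
    "precipitation",
]


@dataclass(frozen=True)
class DailyWeather:
    """One calendar day's surface weather observations.

    Temperatures in degC, humidities in %, wind in m/s, pressure in hPa,
    precipitation in mm.  Requires t_min <= t_mean <= t_max and humidities
    in [0, 100]; NaN fields are allowed and propagate to derived indices.
    """

    date: pd.Timestamp
    t_mean: float
    t_min: float
    t_max: float
    rh_mean: float
    rh_min: float
    rh_max: float
    wind_mean: float
    pressure: float = np.nan
    precipitation: float = np.nan

    def __post_init__(self) -> None:
        ts = (self.t_min, self.t_mean, self.t_max)
        if all(np.isfinite(ts)) and not (ts[0] <= ts[1] <= ts[2]):
            raise ValueError(
                f"temperature ordering violated on {self.date}: "
                f"t_min={ts[0]}, t_mean={ts[1]}, t_max={ts[2]}"
            )
        for name in ("rh_mean", "rh_min", "rh_max"):
            rh = getattr(self, name)
            if np.isfinite(rh) and not 0.0 <= rh <= 100.0:
                raise ValueError(f"{name}={rh} outside [0, 100] on {self.date}")
        if np.isfinite(self.wind_mean) and self.wind_mean < 0:
            raise ValueError(f"negative wind speed {self.wind_mean} on {self.date}")
        if np.isfinite(self.precipitation) and self.precipitation < 0:
            raise ValueError(f"negative precipitation on {self.date}")


@dataclass(frozen=True)
class ComfortIndices:
    """The ten effective-temperature variants for one day, in degC."""

    et1: float
    et2: float
    et3: float
    et4: float
    et5: float
    etw1: float
    etw2: float
    etw3: float
    etw4: float
    etw5: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _check_rh(rh) -> None:
    rh = np.asarray(rh, dtype=float)
    bad = (rh < 0) | (rh > 100)
    if np.any(bad & np.isfinite(rh)):
        raise ValueError("relative humidity outside [0, 100]")


def effective_temperature(t, rh):
    """Effective temperature ET = T - 0.4*(1 - RH/100)*(T - 10).

    Parameters
    ----------
    t : float or array-like
        Air temperature, degC.
    rh : float or array-like
        Relative humidity, percent, in [0, 100].

    Returns
    -------
    float or ndarray
        Effective temperature in degC.  NaN inputs propagate.

    Notes
    -----
    ET equals T at saturation (RH=100) and equals 10 degC when T=10
    regardless of humidity; for T > 10 the dryness correction is
    nonnegative, so ET <= T.
    """
    _check_rh(rh)
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    out = t - 0.4 * (1.0 - rh / 100.0) * (t - 10.0)
    return float(out) if out.ndim == 0 else out


def effective_temperature_wind(t, rh, v, form: EtwForm = "division"):
    """Wind-adjusted effective temperature ETw.

    The default ``form="division"`` evaluates

    .. math::
        ETw = 37 - \\frac{37 - T}{0.68 - 0.0014\\,RH + 1/(1.76 + 1.4 v^{0.75})}
              - 0.29\\,T\\,(1 - RH/100)

    ``form="as_printed"`` multiplies ``(37 - T)`` by the same bracket
    instead of dividing, reproducing a typographic variant of the formula
    that appears in print.  Both forms return 37 at T=37, RH=100.

    Parameters
    ----------
    t, rh : float or array-like
        Air temperature (degC) and relative humidity (%).
    v : float or array-like
        Wind speed, m/s, nonnegative.
    form : {"division", "as_printed"}
        Parenthesization variant.
    """
    _check_rh(rh)
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((v < 0) & np.isfinite(v)):
        raise ValueError("negative wind speed")
    if form not in ("division", "as_printed"):
        raise ValueError(f"unknown ETw form {form!r}")
    bracket = 0.68 - 0.0014 * rh + 1.0 / (1.76 + 1.4 * np.power(v, 0.75))
    if form == "division":
        core = 37.0 - (37.0 - t) / bracket
    else:
        core = 37.0 - (37.0 - t) * bracket
    out = core - 0.29 * t * (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out


def comfort_suite(w: DailyWeather, etw_form: EtwForm = "division") -> ComfortIndices:
    """Compute all ten ET/ETw variants for one day.

    Missing (NaN) weather fields propagate into the affected indices; an
    index is never silently substituted with zero.
    """
    values: dict[str, float] = {}
    for k, (t_col, rh_col) in PAIRINGS.items():
        t = getattr(w, t_col)
        rh = getattr(w, rh_col)
        values[f"et{k}"] = effective_temperature(t, rh)
        values[f"etw{k}"] = effective_temperature_wind(t, rh, w.wind_mean, form=etw_form)
    return ComfortIndices(**values)


def comfort_table(weather: pd.DataFrame, etw_form: EtwForm = "division") -> pd.DataFrame:
    """Vectorized :func:`comfort_suite` over a weather table.

    Parameters
    ----------
    weather : DataFrame
        One row per day with the ``DailyWeather`` columns (``t_mean``,
        ``t_min``, ``t_max``, ``rh_mean``, ``rh_min``, ``rh_max``,
        ``wind_mean``); a ``date`` column, if present, is carried through
        as the index of the result.

    Returns
    -------
    DataFrame
        Columns ``et1..et5, etw1..etw5`` aligned to the input rows.
    """
    out = pd.DataFrame(index=weather.index)
    for k, (t_col, rh_col) in PAIRINGS.items():
        t = weather[t_col].to_numpy(dtype=float)
        rh = weather[rh_col].to_numpy(dtype=float)
        v = weather["wind_mean"].to_numpy(dtype=float)
        out[f"et{k}"] = effective_temperature(t, rh)
        out[f"etw{k}"] = effective_temperature_wind(t, rh, v, form=etw_form)
    if "date" in weather.columns:
        out.insert(0, "date", weather["date"].to_numpy())
    return out


class ThermalComfortTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping daily weather to comfort indices.

    A scikit-learn ``TransformerMixin`` so the comfort step composes with
    pipelines; ``fit`` only validates the input schema.

    Parameters
    ----------
    etw_form : {"division", "as_printed"}
        Parenthesization variant of the wind-adjusted formula.
    """

    def __init__(self, etw_form: EtwForm = "division"):
        self.etw_form = etw_form

    def fit(self, X: pd.DataFrame, y=None) -> "ThermalComfortTransformer":
        missing = [c for c in ("t_mean", "t_min", "t_max", "rh_mean", "rh_min",
                               "rh_max", "wind_mean") if c not in X.columns]
        if missing:
            raise ValueError(f"weather table lacks columns: {missing}")
        self.n_features_in_ = X.shape[1]
        self.feature_names_out_ = [f"et{k}" for k in PAIRINGS] + [
            f"etw{k}" for k in PAIRINGS
        ]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return comfort_table(X, etw_form=self.etw_form)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_)
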