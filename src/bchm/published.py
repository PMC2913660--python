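"""Reference coefficient sets and admission-increase tables.

These constants describe the Sao Paulo (1997-2000, children under 13)
respiratory-admission models that this package re-implements: one Poisson
model per disease group — URI (upper respiratory infections), LRI (lower
respiratory infections and chronic lower respiratory disease), IP
(influenza and pneumonia) — each with the exposure set selected by lag
screening and the published per-unit coefficients.

Two coefficient conventions coexist in the published record:

* ``MODEL_COEFFICIENTS`` — the coefficients as printed with the fitted
  models (per ug/m3, per ppm for CO, per degC for ETw4);
* ``INCREASE_TABLES`` — the percent admission-increase ledgers over eight
  exposure increments.  Inverting any row's first cell (``ln(1+AI/100)/X``
  rounded to three decimals) yields a coefficient that regenerates the
  entire row to one decimal; for some rows (URI, IP ETw4) that implied
  coefficient differs from the printed model coefficient, and the
  increase tables are the internally consistent set.

``EXPOSURE_SETS`` records each group's covariates with their selected
lags (lag k pairs admissions on day t with exposure on day t-k).
"""

from __future__ import annotations

from .risk import invert_increase

__all__ = [
    "DISEASE_GROUPS",
    "EXPOSURE_SETS",
    "MODEL_COEFFICIENTS",
    "INTERCEPTS",
    "INCREASE_TABLES",
    "SUMMARY_INCREASES",
    "implied_coefficient",
]

DISEASE_GROUPS = ("URI", "LRI", "IP")

#: exposure covariate -> selected lag (days), per disease group
EXPOSURE_SETS: dict[str, list[tuple[str, int]]] = {
    "URI": [("so2", 0), ("co", 0), ("etw4", 4)],
    "LRI": [("pm10", 0), ("o3", 3), ("etw4", 3)],
    "IP": [("pm10", 0), ("etw4", 3)],
}

#: printed per-unit Poisson coefficients, by group and covariate
MODEL_COEFFICIENTS: dict[str, dict[str, float]] = {
    "URI": {"so2": 0.009, "co": 0.023, "etw4": -0.007},
    "LRI": {"pm10": 0.001, "o3": 0.002, "etw4": -0.012},
    "IP": {"pm10": 0.002, "etw4": -0.001},
}

#: printed model intercepts (log daily admissions at zero covariates)
INTERCEPTS: dict[str, float] = {"URI": 0.916, "LRI": 1.661, "IP": 3.828}

#: published admission-increase ledgers: covariate -> (unit_step, 8 cells, unit)
INCREASE_TABLES: dict[str, dict[str, tuple[float, list[float], str]]] = {
    "URI": {
        "so2": (10.0, [13.9, 29.7, 47.7, 68.2, 91.6, 118.1, 148.4, 182.9], "ug/m3"),
        "co": (2.0, [9.0, 18.8, 29.4, 41.1, 53.7, 67.5, 82.6, 99.0], "ppm"),
        "etw4": (2.0, [-2.2, -4.3, -6.4, -8.4, -10.4, -12.4, -14.3, -16.1], "degC"),
    },
    "LRI": {
        "pm10": (20.0, [2.0, 4.1, 6.2, 8.3, 10.5, 12.7, 15.0, 17.4], "ug/m3"),
        "o3": (40.0, [8.3, 17.4, 27.1, 37.7, 49.2, 61.6, 75.1, 89.6], "ug/m3"),
        "etw4": (2.0, [-1.6, -3.1, -4.7, -6.2, -7.7, -9.2, -10.6, -12.0], "degC"),
    },
    "IP": {
        "pm10": (20.0, [4.1, 8.3, 12.7, 17.4, 22.1, 27.1, 32.3, 37.7], "ug/m3"),
        "etw4": (2.0, [-3.9, -7.7, -11.3, -14.8, -18.1, -21.3, -24.4, -27.4], "degC"),
    },
}

#: headline summary increases quoted with the tables: (group, covariate,
#: exposure change, percent) — e.g. 182.9% for URI at +80 ug/m3 SO2
SUMMARY_INCREASES: list[tuple[str, str, float, float]] = [
    ("URI", "so2", 80.0, 182.9),
    ("URI", "co", 16.0, 99.0),
    ("LRI", "pm10", 160.0, 17.4),
    ("LRI", "o3", 160.0, 37.7),
    ("LRI", "o3", 320.0, 89.6),
    ("IP", "pm10", 160.0, 37.7),
]


def implied_coefficient(group: str, covariate: str) -> float:
    """Coefficient implied by a published increase row's first cell.

    ``ln(1 + AI_1/100) / unit_step`` rounded to three decimals; the
    convention under which the full printed row is self-consistent.
    """
    unit_step, cells, _ = INCREASE_TABLES[group][covariate]
    return invert_increase(cells[0], unit_step)
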