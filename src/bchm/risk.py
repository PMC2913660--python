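"""Relative risk and percent admission-increase metrics.

For a Poisson log-linear admission model, a coefficient ``beta`` (per unit
of exposure) implies, for an exposure change ``X``:

* relative risk        RR  = exp(beta * X)
* admission increase   AI% = (exp(beta * X) - 1) * 100
* 95% CI for RR at X   exp(X * (beta +/- 1.96 * se))

Published admission-increase ledgers report AI over a grid of exposure
increments (e.g. 10, 20, ..., 80 ug/m3 for SO2) with one decimal, rounding
halves away from zero.  :func:`invert_increase` recovers the coefficient
from a printed AI cell; rounding the recovered coefficient to three
decimals is the convention under which a whole printed row regenerates
from its first cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "RiskTable",
    "round_half_away",
    "relative_risk",
    "admission_increase",
    "rr_confidence_interval",
    "increase_table",
    "invert_increase",
]


def round_half_away(x: float, dp: int = 1) -> float:
    """Round to ``dp`` decimals with ties going away from zero.

    Matches the convention of published risk tables (e.g. -16.15 -> -16.2),
    unlike banker's rounding.
    """
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def relative_risk(beta: float, x: float) -> float:
    """RR = exp(beta * x) for an exposure change ``x``."""
    return float(np.exp(beta * x))


def admission_increase(beta: float, x: float, round_dp: int | None = 1) -> float:
    """Percent admission increase AI = (exp(beta*x) - 1) * 100.

    Reported to one decimal by default (``round_dp=None`` returns the
    unrounded value); negative coefficients yield negative percentages
    (decreases).
    """
    ai = (relative_risk(beta, x) - 1.0) * 100.0
    return ai if round_dp is None else round_half_away(ai, round_dp)


def rr_confidence_interval(
    beta: float, se: float, x: float, as_printed: bool = False
) -> tuple[float, float]:
    """95% confidence interval for the relative risk at exposure change x.

    Default: exp(x * (beta +/- 1.96 se)), the interval of RR = exp(beta*x).
    ``as_printed=True`` evaluates exp(beta +/- 1.96 se) without the x
    multiplier — the coefficient-scale variant some sources print — which
    is the CI of RR only at x = 1.
    """
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    if not as_printed:
        lo, hi = x * lo, x * hi
    lo, hi = float(np.exp(lo)), float(np.exp(hi))
    return (lo, hi) if lo <= hi else (hi, lo)


@dataclass
class RiskTable:
    """Admission-increase ledger for one covariate over an exposure grid.

    ``increase_pct`` is rounded to one decimal (half away from zero) as in
    published tables; ``rr`` is unrounded, so ``(rr - 1) * 100`` recovers
    the increase before rounding.
    """

    covariate: str
    unit_step: float
    grid: list[float]
    increase_pct: list[float]
    rr: list[float]
    ci_low: list[float] = field(default_factory=list)
    ci_high: list[float] = field(default_factory=list)


def increase_table(
    beta: float,
    unit_step: float,
    n_steps: int = 8,
    covariate: str = "",
    se: float | None = None,
) -> RiskTable:
    """Build the admission-increase row for one covariate.

    The exposure grid is ``unit_step * {1, ..., n_steps}``; each cell is
    the percent increase for a change from 0 to that grid value.  When a
    standard error is supplied, 95% CI bounds for RR are included.
    """
    if not unit_step > 0:
        raise ValueError(f"unit_step must be positive, got {unit_step}")
    grid = [unit_step * k for k in range(1, n_steps + 1)]
    rr = [relative_risk(beta, x) for x in grid]
    ai = [admission_increase(beta, x) for x in grid]
    ci_low: list[float] = []
    ci_high: list[float] = []
    if se is not None:
        for x in grid:
            lo, hi = rr_confidence_interval(beta, se, x)
            ci_low.append(lo)
            ci_high.append(hi)
    return RiskTable(
        covariate=covariate,
        unit_step=unit_step,
        grid=grid,
        increase_pct=ai,
        rr=rr,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def invert_increase(ai_percent: float, x: float, round_dp: int | None = 3) -> float:
    """Recover the coefficient implied by a printed AI cell.

    beta = ln(1 + AI/100) / x, rounded to ``round_dp`` decimals (default 3,
    the convention under which every cell of a printed row follows from
    its first increment).
    """
    if ai_percent <= -100:
        raise ValueError("admission increase must exceed -100%")
    if x == 0:
        raise ValueError("exposure change x must be nonzero")
    beta = math.log1p(ai_percent / 100.0) / x
    return beta if round_dp is None else round(beta, round_dp)
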