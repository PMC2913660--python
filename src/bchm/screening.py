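"""Lag screening: pick each covariate's most predictive exposure lag.

Every environmental covariate is shifted by 0-7 days (lag k pairs the
admission count on day t with the exposure on day t-k, the synoptic time
scale) and correlated with the daily admission series.  For each covariate
the selected lag maximizes |r| among the lags whose two-sided Pearson
p-value is below ``alpha``; when no lag is significant the max-|r| lag is
still reported, flagged non-significant.  Ties in |r| break toward the
smaller (more immediate) lag.  Missing days are handled by pairwise
complete-case deletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["LagScreenResult", "lag_series", "pearson_r", "screen", "LagScreener"]


@dataclass(frozen=True)
class LagScreenResult:
    """Best lag for one covariate.

    ``r`` and ``p_value`` are the Pearson correlation and two-sided
    p-value at ``best_lag``; ``n_used`` is the number of complete pairs
    after lag alignment; ``significant`` is False when no screened lag
    reached the significance level.
    """

    covariate: str
    best_lag: int
    r: float
    p_value: float
    n_used: int
    significant: bool


def lag_series(x, k: int, max_lag: int = 7):
    """Shift a daily series so day t carries the value from day t-k.

    The first ``k`` entries become missing.  Accepts a pandas Series
    (index preserved) or array-like (returns float ndarray with NaN).
    """
    if not 0 <= k <= max_lag:
        raise ValueError(f"lag {k} outside [0, {max_lag}]")
    if isinstance(x, pd.Series):
        if len(x) <= k:
            raise ValueError(f"series of length {len(x)} too short for lag {k}")
        return x.shift(k)
    x = np.asarray(x, dtype=float)
    if len(x) <= k:
        raise ValueError(f"series of length {len(x)} too short for lag {k}")
    out = np.full(len(x), np.nan)
    if k == 0:
        out[:] = x
    else:
        out[k:] = x[:-k]
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value.

    Complete-case: pairs with any missing value are dropped.  The p-value
    is the Student-t transform of r on n-2 degrees of freedom.  Raises on
    fewer than 3 complete pairs or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _detrend(s: pd.Series, window: int = 29) -> pd.Series:
    """Remove a centred moving-average seasonal trend."""
    trend = s.rolling(window, center=True, min_periods=window // 2).mean()
    return s - trend


def screen(
    admissions: pd.Series,
    covariates: pd.DataFrame,
    max_lag: int = 7,
    alpha: float = 0.05,
    detrend: bool = False,
) -> list[LagScreenResult]:
    """Screen every covariate over lags 0..max_lag against admissions.

    Parameters
    ----------
    admissions : Series
        Daily counts, aligned by position/index with ``covariates``.
    covariates : DataFrame
        One column per environmental covariate on the same calendar.
    max_lag : int
        Largest lag screened (0 through ``max_lag`` inclusive).
    alpha : float
        Two-sided significance level for flagging.
    detrend : bool
        Remove a centred 29-day moving average from both series before
        correlating (off by default: screening runs on raw series).

    Returns
    -------
    list of LagScreenResult, one per covariate, in column order.
    """
    if covariates.shape[1] == 0:
        raise ValueError("empty covariate set")
    adm = pd.Series(np.asarray(admissions, dtype=float))
    if detrend:
        adm = _detrend(adm)
    results = []
    for name in covariates.columns:
        col = pd.Series(np.asarray(covariates[name], dtype=float))
        if detrend:
            col = _detrend(col)
        rows = []
        for k in range(0, max_lag + 1):
            lagged = lag_series(col, k, max_lag=max_lag)
            r, p = pearson_r(lagged, adm)
            n_used = int(np.sum(np.isfinite(lagged) & np.isfinite(adm)))
            rows.append((k, r, p, n_used))
        signif = [row for row in rows if row[2] < alpha]
        pool = signif if signif else rows
        # max |r|; ties break toward the smaller lag (list is lag-ordered)
        best = max(pool, key=lambda row: abs(row[1]))
        results.append(
            LagScreenResult(
                covariate=name,
                best_lag=best[0],
                r=best[1],
                p_value=best[2],
                n_used=best[3],
                significant=bool(signif),
            )
        )
    return results


def screen_table(results: list[LagScreenResult]) -> pd.DataFrame:
    """Tabular view of screening results (one row per covariate)."""
    return pd.DataFrame(
        [
            {
                "covariate": r.covariate,
                "lag": r.best_lag,
                "r": r.r,
                "p": r.p_value,
                "n": r.n_used,
                "significant": r.significant,
            }
            for r in results
        ]
    )


class LagScreener(BaseEstimator):
    """Estimator facade over :func:`screen`.

    ``fit(X, y)`` screens the covariate table ``X`` against the admission
    series ``y``; results land in ``results_`` (list of
    :class:`LagScreenResult`) and ``table_`` (DataFrame).

    Parameters
    ----------
    max_lag : int, default 7
    alpha : float, default 0.05
    detrend : bool, default False
    """

    def __init__(self, max_lag: int = 7, alpha: float = 0.05,
                 detrend: bool = False):
        self.max_lag = max_lag
        self.alpha = alpha
        self.detrend = detrend

    def fit(self, X: pd.DataFrame, y) -> "LagScreener":
        self.results_ = screen(
            pd.Series(np.asarray(y, dtype=float)),
            X,
            max_lag=self.max_lag,
            alpha=self.alpha,
            detrend=self.detrend,
        )
        self.table_ = screen_table(self.results_)
        self.best_lags_ = {r.covariate: r.best_lag for r in self.results_}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return ``X`` with each covariate shifted to its selected lag."""
        if not hasattr(self, "results_"):
            raise ValueError("LagScreener is not fitted")
        out = pd.DataFrame(index=X.index)
        for r in self.results_:
            out[f"{r.covariate}_lag{r.best_lag}"] = lag_series(
                X[r.covariate], r.best_lag, max_lag=self.max_lag
            )
        return out
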