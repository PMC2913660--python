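"""Poisson log-linear regression fitted by iteratively reweighted least squares.

The admission model for one disease group is

.. math:: \\log E[Y_t] = \\alpha + \\sum_c \\beta_c\\, x_c(t - \\ell_c)
          + \\text{calendar terms}

with Poisson-distributed daily counts.  Calendar adjustment uses dummy
variables for day of week (reference Monday), month (reference January)
and holidays, optionally a nonrespiratory-admissions covariate and a
natural-spline trend on the day index standing in for a nonparametric
seasonality smoother.

Fitting is a hand-written IRLS/Fisher-scoring loop with step-halving that
guarantees a non-increasing deviance; standard errors come from the
inverse Fisher information at the optimum.  ``PoissonRegression`` wraps
the fitter as a scikit-learn estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, interpolate
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DesignSpec",
    "PoissonFit",
    "CollinearityWarning",
    "build_design",
    "spline_trend_basis",
    "fit_irls",
    "deviance",
    "pearson_residuals",
    "PoissonRegression",
]

MAX_LOG_MU = 30.0  # exp(30) ~ 1e13 admissions/day: anything above is divergence


class CollinearityWarning(UserWarning):
    """Raised when two design columns are nearly linearly dependent."""


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of one disease-group model design.

    Parameters
    ----------
    exposure_terms : list of (covariate, lag)
        Exposure columns; ``lag`` in days, 0 meaning same-day pairing.
    day_of_week, month, holiday : bool
        Calendar dummy blocks (references: Monday, January, non-holiday).
    nonrespiratory : bool
        Include a daily nonrespiratory-admissions covariate if the data
        provide a ``nonresp`` column.
    trend_df : int or None
        Degrees of freedom of an optional natural cubic spline trend on
        the day index (None disables the trend, the default).
    """

    exposure_terms: tuple[tuple[str, int], ...]
    day_of_week: bool = True
    month: bool = True
    holiday: bool = True
    nonrespiratory: bool = False
    trend_df: int | None = None

    def __post_init__(self) -> None:
        terms = list(self.exposure_terms)
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate (covariate, lag) pairs in exposure_terms")
        for cov, lag in terms:
            if not 0 <= lag <= 7:
                raise ValueError(f"lag {lag} for {cov} outside [0, 7]")
        object.__setattr__(self, "exposure_terms", tuple(terms))


@dataclass
class PoissonFit:
    """Result of one Poisson model fit."""

    beta: np.ndarray
    se: np.ndarray
    columns: list[str]
    deviance: float
    pearson_chi2: float
    n_obs: int
    converged: bool
    n_iter: int
    mu: np.ndarray = field(repr=False, default=None)

    def coef_table(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se, "z": z}, index=self.columns
        )

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "deviance": float(self.deviance),
            "pearson_chi2": float(self.pearson_chi2),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PoissonFit":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            columns=list(d["columns"]),
            deviance=float(d["deviance"]),
            pearson_chi2=float(d["pearson_chi2"]),
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
        )


def spline_trend_basis(n_days: int, df: int) -> np.ndarray:
    """Natural-ish cubic B-spline basis on the day index, ``df`` columns.

    Interior knots at quantiles of 0..n_days-1; columns are centred so
    the basis is orthogonal to the intercept in the balanced case.
    """
    if df < 2:
        raise ValueError("trend_df must be >= 2")
    t = np.arange(n_days, dtype=float)
    n_inner = max(df - 3, 0)
    inner = np.quantile(t, np.linspace(0, 1, n_inner + 2)[1:-1]) if n_inner else []
    knots = np.concatenate([[t[0]] * 4, inner, [t[-1]] * 4])
    n_basis = len(knots) - 4
    design = np.empty((n_days, n_basis))
    for j in range(n_basis):
        coeffs = np.zeros(n_basis)
        coeffs[j] = 1.0
        design[:, j] = interpolate.BSpline(knots, coeffs, 3)(t)
    design = design[:, 1:]  # drop one column absorbed by the intercept
    return design - design.mean(axis=0)


def _lagged(series: pd.Series, lag: int) -> pd.Series:
    return series.shift(lag)


def build_design(
    data: pd.DataFrame, spec: DesignSpec, response: str = "count"
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the (X, y) design for one model.

    Parameters
    ----------
    data : DataFrame
        Daily table with a ``date`` column, the response column, exposure
        covariate columns, and (if calendar adjustment is on) a
        ``holiday`` 0/1 column.  Rows must be consecutive calendar days.
    spec : DesignSpec
    response : str
        Name of the count column to model.

    Returns
    -------
    (X, y)
        ``X`` has an explicit ``intercept`` column, exposures named
        ``{covariate}_lag{k}``, then dummy blocks in a deterministic
        order.  Rows with any missing value (including the first ``k``
        days of each lagged exposure) are dropped from both.
    """
    if response not in data.columns:
        raise ValueError(f"response column {response!r} not in data")
    date = pd.to_datetime(data["date"])
    X = pd.DataFrame(index=data.index)
    X["intercept"] = 1.0
    for cov, lag in spec.exposure_terms:
        if cov not in data.columns:
            raise ValueError(f"exposure covariate {cov!r} not in data")
        X[f"{cov}_lag{lag}"] = _lagged(data[cov], lag)
    if spec.day_of_week:
        dow = date.dt.dayofweek  # Monday=0 is the reference
        for d, name in enumerate(["tue", "wed", "thu", "fri", "sat", "sun"], start=1):
            X[f"dow_{name}"] = (dow == d).astype(float)
    if spec.month:
        month = date.dt.month  # January is the reference
        names = ["feb", "mar", "apr", "may", "jun", "jul", "aug", "sep", "oct",
                 "nov", "dec"]
        for m, name in zip(range(2, 13), names):
            X[f"month_{name}"] = (month == m).astype(float)
    if spec.holiday:
        if "holiday" not in data.columns:
            raise ValueError("holiday adjustment requested but no 'holiday' column")
        X["holiday"] = data["holiday"].astype(float)
    if spec.nonrespiratory:
        if "nonresp" not in data.columns:
            raise ValueError("nonrespiratory adjustment requested but no 'nonresp' column")
        X["nonresp"] = data["nonresp"].astype(float)
    if spec.trend_df is not None:
        basis = spline_trend_basis(len(data), spec.trend_df)
        for j in range(basis.shape[1]):
            X[f"trend_{j + 1}"] = basis[:, j]

    y = pd.to_numeric(data[response], errors="coerce")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]
    _warn_if_near_collinear(X)
    return X, y


def _warn_if_near_collinear(X: pd.DataFrame, threshold: float = 0.99) -> None:
    cols = [c for c in X.columns if c != "intercept" and X[c].std() > 0]
    if len(cols) < 2:
        return
    corr = X[cols].corr().to_numpy()
    iu = np.triu_indices(len(cols), k=1)
    worst = np.argmax(np.abs(corr[iu]))
    if np.abs(corr[iu][worst]) >= threshold:
        a, b = cols[iu[0][worst]], cols[iu[1][worst]]
        warnings.warn(
            f"design columns {a!r} and {b!r} are nearly collinear "
            f"(|r| = {np.abs(corr[iu][worst]):.3f}); their joint "
            "significance will be unstable",
            CollinearityWarning,
            stacklevel=3,
        )


def deviance(y, mu) -> float:
    """Poisson deviance 2*sum[y*ln(y/mu) - (y - mu)], with 0*ln(0) = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("all fitted means must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def pearson_residuals(y, mu) -> np.ndarray:
    """Pearson residuals (y - mu) / sqrt(mu)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("all fitted means must be positive")
    return (y - mu) / np.sqrt(mu)


def fit_irls(
    X,
    y,
    tol: float = 1e-8,
    max_iter: int = 50,
    columns: list[str] | None = None,
) -> PoissonFit:
    """Maximum-likelihood Poisson fit with log link via IRLS.

    Each iteration solves the weighted least-squares system
    ``(X' W X) b = X' W z`` with weights ``W = diag(mu)`` and working
    response ``z = eta + (y - mu)/mu``.  Step-halving enforces a
    non-increasing deviance; convergence is declared when the relative
    deviance change drops below ``tol``.  Standard errors are
    ``sqrt(diag((X' W X)^{-1}))`` at the optimum.

    Raises
    ------
    ValueError
        If the design is rank-deficient or the linear predictor diverges
        (separation-like behaviour).
    """
    if isinstance(X, pd.DataFrame):
        columns = columns or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        columns = columns or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("response must be nonnegative integer counts")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    # standard GLM initialisation: shrink counts toward the mean
    mu = (y + np.mean(y)) / 2.0
    mu = np.clip(mu, 1e-8, None)
    eta = np.log(mu)
    beta = np.zeros(p)
    dev = deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu
        z = eta + (y - mu) / mu
        wx = X * w[:, None]
        xtwx = X.T @ wx
        xtwz = wx.T @ z
        try:
            beta_new = linalg.solve(xtwx, xtwz, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise ValueError("Fisher information is singular") from exc

        # step-halve until the deviance does not increase; the first
        # iteration leaves the heuristic initialisation, whose deviance is
        # not comparable, so only the overflow guard applies there
        step = beta_new - beta
        frac = 1.0
        for _ in range(30):
            cand = beta + frac * step
            eta_new = X @ cand
            if np.max(eta_new) > MAX_LOG_MU:
                frac /= 2.0
                continue
            mu_new = np.exp(eta_new)
            dev_new = deviance(y, mu_new)
            if it == 1 or dev_new <= dev + 1e-12:
                break
            frac /= 2.0
        else:
            raise ValueError(
                "linear predictor diverged (separation-like behaviour)"
            )
        beta, eta, mu = cand, eta_new, mu_new
        rel = abs(dev - dev_new) / (abs(dev) + 0.1)
        dev = dev_new
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last relative deviance change {rel:.2e})",
            stacklevel=2,
        )

    xtwx = X.T @ (X * mu[:, None])
    cov = linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    chi2 = float(np.sum(pearson_residuals(y, mu) ** 2))
    return PoissonFit(
        beta=beta,
        se=se,
        columns=columns,
        deviance=dev,
        pearson_chi2=chi2,
        n_obs=n,
        converged=converged,
        n_iter=it,
        mu=mu,
    )


class PoissonRegression(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator facade over :func:`fit_irls`.

    Parameters
    ----------
    fit_intercept : bool
        Prepend an intercept column (default True).  Disable when the
        design already carries one.
    tol : float
        Relative deviance-change convergence tolerance.
    max_iter : int
        IRLS iteration cap.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Exposure coefficients (excluding the intercept).
    intercept_ : float
        Fitted intercept (0.0 when ``fit_intercept=False``).
    se_ : ndarray
        Standard errors, intercept first when fitted.
    deviance_, pearson_chi2_ : float
        Goodness-of-fit statistics.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8,
                 max_iter: int = 50):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "PoissonRegression":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per observation in y")
        if self.fit_intercept:
            design = np.column_stack([np.ones(len(y)), X])
            columns = ["intercept"] + names
        else:
            design, columns = X, names
        res = fit_irls(design, y, tol=self.tol, max_iter=self.max_iter,
                       columns=columns)
        self.result_ = res
        if self.fit_intercept:
            self.intercept_ = float(res.beta[0])
            self.coef_ = res.beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = res.beta.copy()
        self.se_ = res.se.copy()
        self.deviance_ = res.deviance
        self.pearson_chi2_ = res.pearson_chi2
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.feature_names_in_ = np.asarray(names)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Expected counts exp(intercept + X @ coef)."""
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return np.exp(self.intercept_ + X @ self.coef_)
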