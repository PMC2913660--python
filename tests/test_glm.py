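"""Design construction and the hand-written Poisson IRLS fitter."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from bchm.datagen import generate_dataset, scenario_for_group
from bchm.glm import (
    CollinearityWarning,
    DesignSpec,
    PoissonFit,
    PoissonRegression,
    build_design,
    deviance,
    fit_irls,
    pearson_residuals,
    spline_trend_basis,
)


def _toy_frame(n=60, seed=3):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("1998-01-01", periods=n)
    x = rng.normal(50, 10, n)
    return pd.DataFrame(
        {
            "date": dates,
            "pm10": x,
            "holiday": (dates.day == 1).astype(int),
            "count": rng.poisson(np.exp(1.0 + 0.005 * x)),
        }
    )


class TestDesign:
    def test_minimal_design_two_columns(self):
        spec = DesignSpec(exposure_terms=(("pm10", 0),), day_of_week=False,
                          month=False, holiday=False)
        X, y = build_design(_toy_frame(), spec)
        assert list(X.columns) == ["intercept", "pm10_lag0"]
        assert len(X) == len(y) == 60

    def test_full_calendar_dummy_count(self):
        spec = DesignSpec(exposure_terms=(("pm10", 0),))
        X, _ = build_design(_toy_frame(400), spec)
        # intercept + exposure + 6 dow + 11 month + holiday
        assert X.shape[1] == 1 + 1 + 6 + 11 + 1
        dow_cols = [c for c in X.columns if c.startswith("dow_")]
        assert "dow_mon" not in X.columns and len(dow_cols) == 6  # Monday ref
        assert "month_jan" not in X.columns  # January reference

    def test_lag_trimming(self):
        frame = _toy_frame(3)
        spec = DesignSpec(exposure_terms=(("pm10", 1),), day_of_week=False,
                          month=False, holiday=False)
        X, y = build_design(frame, spec)
        assert len(X) == 2  # first day lost to the lag

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DesignSpec(exposure_terms=(("pm10", 0), ("pm10", 0)))

    def test_near_collinear_pair_warned(self):
        frame = _toy_frame(300)
        frame["so2"] = 0.35 * frame["pm10"] + 0.01  # exact linear copy
        spec = DesignSpec(exposure_terms=(("pm10", 0), ("so2", 0)),
                          day_of_week=False, month=False, holiday=False)
        with pytest.warns(CollinearityWarning, match="pm10_lag0.*so2_lag0"):
            build_design(frame, spec)

    def test_spline_trend_columns(self):
        spec = DesignSpec(exposure_terms=(("pm10", 0),), day_of_week=False,
                          month=False, holiday=False, trend_df=5)
        X, _ = build_design(_toy_frame(200), spec)
        trend = [c for c in X.columns if c.startswith("trend_")]
        assert len(trend) >= 3
        basis = spline_trend_basis(200, 5)
        assert basis.shape[0] == 200
        np.testing.assert_allclose(basis.mean(axis=0), 0.0, atol=1e-10)


class TestDeviance:
    def test_perfect_fit_zero(self):
        y = np.array([3.0, 1.0, 7.0])
        assert deviance(y, y) == 0.0
        np.testing.assert_allclose(pearson_residuals(y, y), 0.0)

    def test_hand_evaluated_case(self):
        assert deviance([2.0], [1.0]) == pytest.approx(2 * (2 * np.log(2) - 1))

    def test_zero_count_term(self):
        # y=0 contributes 2*mu
        assert deviance([0.0], [3.0]) == pytest.approx(6.0)

    def test_positive_mu_required(self):
        with pytest.raises(ValueError, match="positive"):
            deviance([1.0], [0.0])
        with pytest.raises(ValueError, match="positive"):
            pearson_residuals([1.0], [-1.0])


class TestIRLS:
    def test_intercept_only_closed_form(self):
        fit = fit_irls(np.ones((3, 1)), [1, 2, 3])
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-10)
        assert fit.converged

    def test_saturated_two_group_closed_form(self):
        X = np.column_stack([np.ones(4), [0.0, 0.0, 1.0, 1.0]])
        fit = fit_irls(X, [2, 2, 6, 6])
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-10)
        assert fit.beta[1] == pytest.approx(np.log(3.0), abs=1e-10)

    def test_score_equation_with_intercept(self, default_frame):
        spec = DesignSpec(exposure_terms=(("pm10", 0), ("etw4", 3)))
        X, y = build_design(default_frame, spec, response="LRI")
        fit = fit_irls(X, y)
        assert abs(np.sum(y.to_numpy() - fit.mu)) < 1e-6

    def test_pearson_chi2_near_df_when_well_specified(self, default_frame):
        spec = DesignSpec(exposure_terms=(("pm10", 0), ("o3", 3), ("etw4", 3)))
        X, y = build_design(default_frame, spec, response="LRI")
        fit = fit_irls(X, y)
        ratio = fit.pearson_chi2 / (fit.n_obs - X.shape[1])
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_irls(X, np.ones(10))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative integer"):
            fit_irls(np.ones((3, 1)), [1, -2, 3])

    def test_non_convergence_flagged(self, rng):
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = rng.poisson(np.exp(1 + 0.5 * X[:, 1]))
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_irls(X, y, max_iter=2)
        assert not fit.converged
        assert fit.n_iter == 2
        assert np.all(np.isfinite(fit.beta))

    def test_matches_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        for _ in range(20):
            n = int(rng.integers(30, 120))
            p = int(rng.integers(1, 4))
            X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, p))])
            beta = rng.normal(0, 0.5, p + 1)
            y = rng.poisson(np.exp(np.clip(X @ beta, None, 5)))
            ours = fit_irls(X, y, tol=1e-12, max_iter=100)
            ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=1e-12,
                                                                 maxiter=200)
            np.testing.assert_allclose(ours.beta, ref.params, rtol=1e-7)
            np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-6)
            assert ours.deviance == pytest.approx(ref.deviance, rel=1e-8)
            assert ours.pearson_chi2 == pytest.approx(ref.pearson_chi2, rel=1e-8)

    def test_fit_roundtrips_through_json_dict(self):
        fit = fit_irls(np.ones((4, 1)), [2, 3, 4, 3])
        back = PoissonFit.from_dict(fit.to_dict())
        np.testing.assert_allclose(back.beta, fit.beta)
        assert back.columns == fit.columns


class TestEstimator:
    def test_sklearn_facade_matches_fit_irls(self, rng):
        X = rng.normal(size=(200, 2))
        y = rng.poisson(np.exp(1.0 + 0.3 * X[:, 0] - 0.2 * X[:, 1]))
        est = PoissonRegression().fit(pd.DataFrame(X, columns=["a", "b"]), y)
        raw = fit_irls(np.column_stack([np.ones(200), X]), y)
        assert est.intercept_ == pytest.approx(raw.beta[0])
        np.testing.assert_allclose(est.coef_, raw.beta[1:])
        np.testing.assert_allclose(est.predict(X), raw.mu)
        assert est.converged_ and est.deviance_ == pytest.approx(raw.deviance)

    def test_get_set_params_clone(self):
        from sklearn.base import clone

        est = PoissonRegression(tol=1e-6, max_iter=10)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_predict_requires_fit(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            PoissonRegression().predict(np.ones((2, 1)))


def test_collinearity_degrades_joint_significance():
    """With PM10-SO2 correlation 0.95, joint modelling costs significance.

    The single-pollutant fits see a strong association for each pollutant;
    jointly the shared variance inflates both standard errors.
    """
    cfg = dataclasses.replace(scenario_for_group("URI", seed=11),
                              collinearity_rho=0.95)
    ds = generate_dataset(cfg)
    from bchm.datagen import modelling_frame

    frame = modelling_frame(ds)

    def z(terms, col):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CollinearityWarning)
            X, y = build_design(frame, DesignSpec(exposure_terms=terms),
                                response="URI")
            fit = fit_irls(X, y)
        i = fit.columns.index(col)
        return abs(fit.beta[i] / fit.se[i])

    single = z((("so2", 0), ("co", 0), ("etw4", 4)), "so2_lag0")
    joint_terms = (("so2", 0), ("pm10", 0), ("co", 0), ("etw4", 4))
    joint = z(joint_terms, "so2_lag0")
    assert joint < single  # shared variance dilutes the SO2 signal
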