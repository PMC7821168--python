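"""Covariate-adjusted ROC: worked example, step-by-step oracle, null
behaviour and reduction to the pooled empirical ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipdmeta import aroc, dataio
from ipdmeta.accuracy import empirical_roc
from ipdmeta.aroc import (
    aroc_curve_table,
    covariate_distributions,
    fit_aroc,
    per_study_regressions,
)

from conftest import make_dataset


def make_cov_dataset(rows):
    return make_dataset(
        rows,
        columns=["Study", "test.results", "disease", "age"],
        covariate_types={"age": "continuous"},
    )


def oracle_aroc(y_nd, x_nd, y_d, x_d):
    """Step-by-step reference: explicit loops, no shared code with fit_aroc."""
    x_nd = np.column_stack([np.ones(len(y_nd)), x_nd]) if x_nd is not None else np.ones((len(y_nd), 1))
    x_d = np.column_stack([np.ones(len(y_d)), x_d]) if x_d is not None else np.ones((len(y_d), 1))
    beta = np.linalg.solve(x_nd.T @ x_nd, x_nd.T @ np.asarray(y_nd))
    resid = np.asarray(y_nd) - x_nd @ beta
    sigma = np.sqrt(sum(r * r for r in resid) / (len(y_nd) - x_nd.shape[1]))
    z = resid / sigma
    placements = []
    for yi, xi in zip(y_d, x_d):
        zi = (yi - xi @ beta) / sigma
        f = sum(1 for v in z if v <= zi) / len(z)  # right-continuous ECDF
        placements.append(1 - f)
    return beta, sigma, np.array(placements), 1 - np.mean(placements)


class TestWorkedExample:
    def test_intercept_only_hand_computation(self):
        """Nondiseased {1,2,3}, diseased {2.5}: b0=2, sigma=1, residuals
        {-1,0,1}, F(0.5)=2/3, U=1/3, AAUC=2/3."""
        rows = [("A", 1.0, 0), ("A", 2.0, 0), ("A", 3.0, 0), ("A", 2.5, 1)]
        data = make_dataset(rows)
        fit = fit_aroc(data, covariate=None)
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.sigma_hat == pytest.approx(1.0)
        np.testing.assert_allclose(fit.standardized_residuals, [-1, 0, 1])
        assert fit.placement_values[0] == pytest.approx(1 / 3)
        assert fit.aauc == pytest.approx(2 / 3)

    def test_matches_independent_step_by_step_oracle(self):
        rng = np.random.default_rng(4)
        n_nd, n_d = 120, 60
        x_nd = rng.normal(50, 10, n_nd)
        x_d = rng.normal(52, 10, n_d)
        y_nd = 1 + 0.05 * x_nd + rng.normal(0, 1, n_nd)
        y_d = 2.5 + 0.05 * x_d + rng.normal(0, 1, n_d)
        rows = [("A", y, 0, x) for y, x in zip(y_nd, x_nd)]
        rows += [("A", y, 1, x) for y, x in zip(y_d, x_d)]
        fit = fit_aroc(make_cov_dataset(rows), "age")
        beta, sigma, placements, aauc = oracle_aroc(y_nd, x_nd, y_d, x_d)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        assert fit.sigma_hat == pytest.approx(sigma, abs=1e-12)
        np.testing.assert_allclose(np.sort(fit.placement_values), np.sort(placements), atol=1e-12)
        assert fit.aauc == pytest.approx(aauc, abs=1e-12)


class TestAROCProperties:
    @staticmethod
    def _null_dataset(n=2000, seed=0, effect=0.0, gamma=0.5):
        rng = np.random.default_rng(seed)
        x = rng.normal(50, 10, n)
        dis = rng.integers(0, 2, n)
        y = 1 + gamma * (x - 50) / 10 + effect * dis + rng.normal(0, 1, n)
        rows = list(zip(np.repeat(["A", "B"], n // 2), y, dis, x))
        return make_cov_dataset(rows)

    def test_null_aauc_near_half(self):
        fit = fit_aroc(self._null_dataset(seed=6), "age")
        assert fit.aauc == pytest.approx(0.5, abs=0.03)

    def test_placement_values_uniform_under_null(self):
        fit = fit_aroc(self._null_dataset(seed=17), "age")
        stat = stats.kstest(fit.placement_values, "uniform").statistic
        assert stat < 0.05

    def test_zero_covariate_effect_reduces_to_pooled_roc(self):
        data = self._null_dataset(seed=8, effect=1.5, gamma=0.0)
        fit = fit_aroc(data, "age")
        d, nd = data.test_values()
        pooled = empirical_roc(d, nd)
        grid = np.linspace(0, 1, 401)
        aroc_vals = fit.curve(grid)
        pooled_interp = np.interp(grid, pooled[:, 0], pooled[:, 1])
        assert np.max(np.abs(aroc_vals - pooled_interp)) < 0.03

    def test_affine_invariance_of_aauc(self):
        data = self._null_dataset(seed=9, effect=1.5)
        fit = fit_aroc(data, "age")
        frame = data.frame.copy()
        frame["test_result"] = 3.0 * frame["test_result"] - 7.0
        data2 = dataio.IPDDataset(frame, data.covariate_types, data.flagged_studies)
        fit2 = fit_aroc(data2, "age")
        assert fit2.aauc == pytest.approx(fit.aauc, abs=1e-12)

    def test_curve_bounds_and_monotonicity(self):
        fit = fit_aroc(self._null_dataset(seed=10, effect=1.0), "age")
        tab = aroc_curve_table(fit)
        assert tab["aroc"].iloc[0] <= 0.05
        assert tab["aroc"].iloc[-1] == 1.0
        assert (np.diff(tab["aroc"]) >= 0).all()

    def test_aauc_equals_trapezoid_of_curve(self):
        fit = fit_aroc(self._null_dataset(seed=12, effect=1.0), "age")
        grid = np.linspace(0, 1, 2001)
        integral = np.trapezoid(fit.curve(grid), grid)
        assert integral == pytest.approx(fit.aauc, abs=1.0 / fit.n_diseased)

    def test_slope_recovery(self):
        """Generating model y = 1 + 0.5 x + N(0,1) with disease shift 1.5."""
        rng = np.random.default_rng(14)
        n = 2000
        x = rng.normal(0, 1, n)
        dis = rng.integers(0, 2, n)
        y = 1 + 0.5 * x + 1.5 * dis + rng.normal(0, 1, n)
        data = make_cov_dataset(list(zip(["A"] * n, y, dis, x)))
        fit = fit_aroc(data, "age")
        assert fit.coefficients[1] == pytest.approx(0.5, abs=0.1)

    def test_categorical_covariate_indicator_coding(self):
        rng = np.random.default_rng(15)
        n = 400
        sex = rng.choice(["f", "m"], n)
        dis = rng.integers(0, 2, n)
        y = 1 + 0.8 * (sex == "m") + 1.2 * dis + rng.normal(0, 1, n)
        data = make_dataset(
            list(zip(["A"] * n, y, dis, sex)),
            columns=["Study", "test.results", "disease", "sex"],
        )
        fit = fit_aroc(data, "sex")
        assert fit.coefficient_names == ("intercept", "sex[m]")
        assert fit.coefficients[1] == pytest.approx(0.8, abs=0.3)
        assert 0.5 < fit.aauc <= 1.0

    def test_design_too_small_rejected(self):
        rows = [("A", 1.0, 0, 5.0), ("A", 2.0, 0, 6.0), ("A", 3.0, 1, 7.0)]
        with pytest.raises(aroc.DesignError):
            fit_aroc(make_cov_dataset(rows), "age")


class TestRegressions:
    def test_exact_line(self):
        rows = [("A", 1.0, 0, 0.0), ("A", 3.0, 0, 1.0), ("A", 5.0, 1, 2.0)]
        fits = per_study_regressions(make_cov_dataset(rows), "age")
        assert len(fits) == 1
        assert fits[0].slope == pytest.approx(2.0)
        assert fits[0].intercept == pytest.approx(1.0)
        assert fits[0].r_squared == pytest.approx(1.0)

    def test_constant_covariate_skipped(self):
        rows = [("A", 1.0, 0, 5.0), ("A", 2.0, 0, 5.0), ("A", 3.0, 1, 5.0)]
        assert per_study_regressions(make_cov_dataset(rows), "age") == []

    def test_categorical_covariate_rejected(self, example_data):
        with pytest.raises(TypeError, match="categorical"):
            per_study_regressions(example_data, "sex")

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(16)
        x = rng.normal(0, 2, 50)
        y = 2 - 1.5 * x + rng.normal(0, 0.5, 50)
        rows = [("A", yi, i % 2, xi) for i, (yi, xi) in enumerate(zip(y, x))]
        fit = per_study_regressions(make_cov_dataset(rows), "age")[0]
        X = np.column_stack([np.ones(50), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)


class TestCovariateDistributions:
    def test_balanced_categorical_levels(self):
        rows = [("A", 1.0, 1, "x"), ("A", 2.0, 1, "y"), ("A", 3.0, 0, "x"), ("A", 4.0, 0, "y")]
        out = covariate_distributions(
            make_dataset(rows, columns=["Study", "test.results", "disease", "sex"]), "sex"
        )
        assert set(out["percent"]) == {50.0}

    def test_continuous_density_integrates_to_one(self, example_data):
        out = covariate_distributions(example_data, "age")
        for (_, _), grp in out.groupby(["study", "group"]):
            area = np.trapezoid(grp["density"], grp["x"])
            assert area == pytest.approx(1.0, abs=1e-2)

    def test_constant_covariate_falls_back_to_categorical(self):
        rows = [("A", float(i), i % 2, 7.7) for i in range(6)]
        out = covariate_distributions(make_cov_dataset(rows), "age")
        assert "level" in out.columns
        assert set(out["percent"]) == {100.0}

    def test_unknown_covariate_lists_available(self, example_data):
        with pytest.raises(KeyError, match="age"):
            covariate_distributions(example_data, "bmi")
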