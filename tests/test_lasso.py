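import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cohortlasso as cl
from conftest import orthonormal_design, random_gaussian_design


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "value,threshold,expected",
        [(2.0, 0.5, 1.5), (-0.3, 0.5, 0.0), (-2.0, 0.5, -1.5), (0.5, 0.5, 0.0)],
    )
    def test_analytic_values(self, value, threshold, expected):
        assert cl.soft_threshold(value, threshold) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            cl.soft_threshold(1.0, -0.1)

    @given(value=st.floats(-100, 100), threshold=st.floats(0, 50))
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_shrinkage_properties(self, value, threshold):
        out = cl.soft_threshold(value, threshold)
        assert abs(out) == max(abs(value) - threshold, 0)
        assert out * value >= 0  # never flips sign


class TestStandardize:
    def test_three_point_column(self):
        design = cl.standardize_matrix(np.array([[1.0], [2.0], [3.0]]), np.zeros(3))
        assert design.z.mean() == pytest.approx(0, abs=1e-15)
        assert design.z.std() == pytest.approx(1, abs=1e-15)

    def test_restandardization_is_identity(self):
        rng = np.random.default_rng(0)
        design = random_gaussian_design(rng)
        again = cl.standardize_matrix(design.z, design.y)
        np.testing.assert_allclose(again.z, design.z, atol=1e-12)

    def test_back_transform_reproduces_raw_least_squares(self):
        rng = np.random.default_rng(1)
        n, p = 40, 5
        x = rng.normal(3, 2, size=(n, p))
        y = rng.normal(size=n)
        design = cl.standardize_matrix(x, y)
        a_std = np.column_stack([np.ones(n), design.z])
        coef_std = np.linalg.lstsq(a_std, y, rcond=None)[0]
        coef_raw = coef_std[1:] / design.scales
        intercept_raw = coef_std[0] - coef_raw @ design.centers
        a_raw = np.column_stack([np.ones(n), x])
        expected = np.linalg.lstsq(a_raw, y, rcond=None)[0]
        np.testing.assert_allclose(intercept_raw, expected[0], atol=1e-8)
        np.testing.assert_allclose(coef_raw, expected[1:], atol=1e-8)

    def test_zero_variance_column_named(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="x0"):
            cl.standardize_matrix(x, np.zeros(10))


class TestLambdaGrid:
    def test_boundary_behavior_by_fitting(self):
        rng = np.random.default_rng(2)
        design = random_gaussian_design(rng)
        lmax = cl.lambda_max(design, "gaussian")
        at_top = cl.fit_path(design, grid=np.array([lmax]))
        assert (at_top.coef_std == 0).all()
        just_below = cl.fit_path(design, grid=np.array([0.99 * lmax]))
        assert (just_below.coef_std != 0).any()

    def test_single_point_grid_is_lambda_max(self):
        rng = np.random.default_rng(3)
        design = random_gaussian_design(rng)
        grid = cl.lambda_grid(design, "gaussian", n_lambda=1)
        assert grid.shape == (1,)
        assert grid[0] == pytest.approx(cl.lambda_max(design, "gaussian"))

    def test_lambda_max_is_homogeneous_in_y(self):
        rng = np.random.default_rng(4)
        design = random_gaussian_design(rng)
        doubled = cl.StandardizedDesign(
            z=design.z, centers=design.centers, scales=design.scales,
            y=2 * design.y, predictor_names=design.predictor_names,
        )
        assert cl.lambda_max(doubled, "gaussian") == pytest.approx(
            2 * cl.lambda_max(design, "gaussian"), rel=1e-12
        )

    def test_constant_outcome_rejected(self):
        rng = np.random.default_rng(5)
        design = random_gaussian_design(rng)
        design.y = np.ones_like(design.y)
        with pytest.raises(ValueError, match="constant outcome"):
            cl.lambda_grid(design, "gaussian")


class TestFitPath:
    def test_null_fit_intercepts_at_boundary(self, rrr_design):
        gauss = cl.fit_path(rrr_design, grid=cl.lambda_grid(rrr_design, "gaussian")[:1])
        assert gauss.intercept_std[0] == pytest.approx(rrr_design.y.mean(), abs=1e-10)
        binom = cl.fit_path(
            rrr_design, grid=cl.lambda_grid(rrr_design, "binomial")[:1],
            family="binomial",
        )
        prev = rrr_design.y.mean()
        assert binom.intercept_std[0] == pytest.approx(
            np.log(prev / (1 - prev)), abs=1e-6
        )
        assert (binom.coef_std[0] == 0).all()

    def test_objective_nonincreasing_across_sweeps(self):
        # cap the coordinate-update budget at increasing values; each full
        # re-solve from the same cold start must not increase the objective
        rng = np.random.default_rng(6)
        design = random_gaussian_design(rng, n=50, p=8)
        lam = 0.3 * cl.lambda_max(design, "gaussian")

        def objective(path):
            resid = design.y - path.intercept_std[0] - design.z @ path.coef_std[0]
            return 0.5 * np.mean(resid**2) + lam * np.abs(path.coef_std[0]).sum()

        budgets = [8, 16, 24, 40, 80, 400]
        values = [
            objective(cl.fit_path(design, grid=np.array([lam]), max_iter=b))
            for b in budgets
        ]
        assert all(v2 <= v1 + 1e-12 for v1, v2 in zip(values, values[1:]))

    def test_training_deviance_nonincreasing_along_path(self, rrr_design):
        for family in ("gaussian", "binomial"):
            path = cl.fit_path(
                rrr_design, grid=cl.lambda_grid(rrr_design, family), family=family
            )
            assert (np.diff(path.deviance) <= 1e-10).all()

    def test_active_set_grows_near_monotonically(self, rrr_design):
        path = cl.fit_path(
            rrr_design, grid=cl.lambda_grid(rrr_design, "gaussian")
        )
        nnz = path.n_nonzero()
        assert nnz[0] == 0
        assert (np.diff(nnz.astype(int)) >= -1).all()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        n, p = 60, 6
        x = rng.normal(2, 1.5, size=(n, p))
        y = x[:, 0] * 0.8 - x[:, 2] + rng.normal(0, 0.5, size=n)
        c = 7.5
        x_scaled = x.copy()
        x_scaled[:, 1] *= c
        d1 = cl.standardize_matrix(x, y)
        d2 = cl.standardize_matrix(x_scaled, y)
        grid = cl.lambda_grid(d1, "gaussian", n_lambda=20)
        p1 = cl.fit_path(d1, grid=grid)
        p2 = cl.fit_path(d2, grid=grid)
        np.testing.assert_allclose(p2.coef_std, p1.coef_std, atol=1e-8)
        np.testing.assert_allclose(p2.deviance, p1.deviance, atol=1e-8)
        np.testing.assert_allclose(
            p2.coef_raw[:, 1], p1.coef_raw[:, 1] / c, atol=1e-8
        )

    def test_binomial_matches_statsmodels_l1(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n, p = 120, 5
        x = rng.standard_normal((n, p))
        eta = 0.9 * x[:, 0] - 1.1 * x[:, 3]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        design = cl.standardize_matrix(x, y)
        lam = 0.25 * cl.lambda_max(design, "binomial")
        path = cl.fit_path(
            design, grid=np.array([lam]), family="binomial", tol=1e-10
        )
        alpha = np.r_[0.0, np.full(p, n * lam)]
        sm_fit = sm.Logit(y, sm.add_constant(design.z)).fit_regularized(
            method="l1", alpha=alpha, disp=0, acc=1e-12, trim_mode="off"
        )
        np.testing.assert_allclose(path.intercept_std[0], sm_fit.params[0], atol=1e-4)
        np.testing.assert_allclose(path.coef_std[0], sm_fit.params[1:], atol=1e-4)

    def test_nan_design_rejected(self, rrr_design):
        bad = cl.StandardizedDesign(
            z=rrr_design.z.copy(), centers=rrr_design.centers,
            scales=rrr_design.scales, y=rrr_design.y,
            predictor_names=rrr_design.predictor_names,
        )
        bad.z[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cl.fit_path(bad)


class TestPredict:
    def test_null_model_predicts_outcome_mean(self):
        rng = np.random.default_rng(9)
        design = random_gaussian_design(rng)
        lmax = cl.lambda_max(design, "gaussian")
        path = cl.fit_path(design, grid=np.array([lmax]))
        x_new = rng.normal(size=(5, design.k)) * design.scales + design.centers
        pred = cl.predict(path, lmax, x_new)
        np.testing.assert_allclose(pred.linear, design.y.mean(), atol=1e-8)
        assert pred.prob is None

    def test_binomial_probabilities_in_unit_interval(self, rrr_design):
        grid = cl.lambda_grid(rrr_design, "binomial", n_lambda=10)
        path = cl.fit_path(rrr_design, grid=grid, family="binomial")
        x_new = rrr_design.z * rrr_design.scales + rrr_design.centers
        pred = cl.predict(path, grid[5], x_new)
        assert ((pred.prob > 0) & (pred.prob < 1)).all()

    def test_two_predictor_linear_predictor_by_hand(self):
        rng = np.random.default_rng(10)
        design = random_gaussian_design(rng, n=30, p=2, sparsity=2)
        grid = cl.lambda_grid(design, "gaussian", n_lambda=10)
        path = cl.fit_path(design, grid=grid)
        lam = grid[7]
        idx = path.index_of(lam)
        x_new = np.array([[1.2, -0.7], [0.0, 2.0]])
        expected = (
            path.intercept_raw[idx]
            + x_new[:, 0] * path.coef_raw[idx, 0]
            + x_new[:, 1] * path.coef_raw[idx, 1]
        )
        np.testing.assert_allclose(
            cl.predict(path, lam, x_new).linear, expected, atol=1e-12
        )

    def test_unknown_lambda_rejected(self):
        rng = np.random.default_rng(11)
        design = random_gaussian_design(rng)
        path = cl.fit_path(design, grid=cl.lambda_grid(design, "gaussian", n_lambda=5))
        with pytest.raises(KeyError):
            cl.predict(path, 0.123456, design.z)


def test_orthonormal_fixture_is_orthonormal():
    rng = np.random.default_rng(12)
    design = orthonormal_design(rng)
    gram = design.z.T @ design.z / design.n
    np.testing.assert_allclose(gram, np.eye(design.k), atol=1e-10)
    np.testing.assert_allclose(design.z.mean(axis=0), 0, atol=1e-10)
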