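import numpy as np
import pandas as pd
import pytest

from phenoceiling.exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
)
from phenoceiling.io_formats import read_newick
from phenoceiling.phylo_gls import (
    lambda_correlation,
    pgls_confband,
    pgls_fit,
    pgls_loglik,
    pgls_predict_newtip,
)

from conftest import balanced8_correlation

# fixed trait data on the 8-taxon tree, generated once from a seeded
# Brownian simulation and frozen here so the GLS oracle test is static
X8 = pd.Series([-0.6, 0.3, 1.1, 1.9, -0.2, 0.8, 1.4, 2.2],
               index=list("ABCDEFGH"))
Y8 = pd.Series([2.61, 1.35, 0.62, -0.90, 2.32, 1.10, 0.05, -1.12],
               index=list("ABCDEFGH"))


class TestLambdaCorrelation:
    def test_lambda_zero_is_identity(self, tree8):
        _, C = lambda_correlation(tree8, 0.0)
        np.testing.assert_allclose(C, np.eye(8), atol=1e-12)

    def test_lambda_one_is_brownian(self, tree8):
        labels, C = lambda_correlation(tree8, 1.0)
        ref_labels, ref = balanced8_correlation()
        order = [labels.index(s) for s in ref_labels]
        np.testing.assert_allclose(C[np.ix_(order, order)], ref, atol=1e-12)

    def test_triple_half_lambda(self, tree3):
        labels, C = lambda_correlation(tree3, 0.5)
        i, j, k = (labels.index(s) for s in "ABC")
        assert C[i, j] == pytest.approx(0.25)   # 0.5 * (1/2 shared)
        assert C[i, k] == pytest.approx(0.0)
        assert np.all(np.diag(C) == 1.0)

    def test_lambda_out_of_range(self, tree8):
        with pytest.raises(InvalidArgumentError):
            lambda_correlation(tree8, 1.2)


class TestPglsFit:
    def test_star_tree_equals_ols(self):
        star = read_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(42)
        x = pd.Series(rng.uniform(0, 2, 6), index=list("ABCDEF"))
        y = pd.Series(1.0 + 0.5 * x.values + rng.normal(0, 0.1, 6),
                      index=list("ABCDEF"))
        fit = pgls_fit(x, y, star)
        b1, b0 = np.polyfit(x.values, y.values, 1)
        assert fit.intercept == pytest.approx(b0, abs=1e-8)
        assert fit.slope == pytest.approx(b1, abs=1e-8)

    def test_lambda_zero_equals_ols(self, tree8):
        fit = pgls_fit(X8, Y8, tree8, lam=0.0)
        b1, b0 = np.polyfit(X8.values, Y8.values, 1)
        assert fit.intercept == pytest.approx(b0, abs=1e-8)
        assert fit.slope == pytest.approx(b1, abs=1e-8)

    def test_noiseless_line_recovered(self, tree8):
        y = 2.0 + 0.75 * X8
        fit = pgls_fit(X8, y, tree8)
        assert fit.intercept == pytest.approx(2.0, abs=1e-8)
        assert fit.slope == pytest.approx(0.75, abs=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_fixed_lambda_matches_dense_gls_oracle(self, tree8):
        """At lambda=1 the estimate must equal the closed-form GLS
        (X'V^-1 X)^-1 X'V^-1 y computed by dense inversion on the
        hand-built correlation matrix."""
        labels, C = balanced8_correlation()
        X = np.column_stack([np.ones(8), X8[labels].values])
        Vi = np.linalg.inv(C)
        beta = np.linalg.inv(X.T @ Vi @ X) @ (X.T @ Vi @ Y8[labels].values)
        fit = pgls_fit(X8, Y8, tree8, lam=1.0)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)
        # parameter covariance against the same oracle
        resid = Y8[labels].values - X @ beta
        s2 = (resid @ Vi @ resid) / (8 - 2)
        np.testing.assert_allclose(fit.param_cov,
                                   s2 * np.linalg.inv(X.T @ Vi @ X),
                                   atol=1e-8)

    def test_lambda_hat_dominates_grid(self, tree8):
        fit = pgls_fit(X8, Y8, tree8)
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            assert fit.loglik >= pgls_loglik(X8, Y8, tree8, lam) - 1e-6

    def test_too_few_species(self, tree8):
        x = pd.Series([0.0, 1.0], index=["A", "B"])
        with pytest.raises(InsufficientDataError):
            pgls_fit(x, x, tree8)

    def test_constant_predictor(self, tree8):
        x = pd.Series(np.ones(8), index=list("ABCDEFGH"))
        with pytest.raises(DegenerateDesignError):
            pgls_fit(x, Y8, tree8)

    def test_species_not_on_tree_dropped_with_warning(self, tree8):
        x = pd.concat([X8, pd.Series({"Zeta": 1.0})])
        y = pd.concat([Y8, pd.Series({"Zeta": 1.0})])
        with pytest.warns(UserWarning, match="not on tree"):
            fit = pgls_fit(x, y, tree8)
        assert fit.n == 8


class TestConfband:
    def test_zero_variance_zero_width(self, tree8):
        y = 2.0 + 0.75 * X8
        fit = pgls_fit(X8, y, tree8)
        grid = np.linspace(-1, 3, 7)
        mid, lo, hi = pgls_confband(fit, grid, include_residual=True)
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-6)

    def test_width_minimal_near_weighted_mean(self, tree8):
        fit = pgls_fit(X8, Y8, tree8)
        grid = np.linspace(-3, 5, 161)
        _, lo, hi = pgls_confband(fit, grid)
        width = hi - lo
        k = int(np.argmin(width))
        assert -1.0 < grid[k] < 3.0  # interior, near the data centroid
        # width grows monotonically away from the minimum
        assert np.all(np.diff(width[:k + 1]) <= 1e-12)
        assert np.all(np.diff(width[k:]) >= -1e-12)

    def test_nested_levels(self, tree8):
        fit = pgls_fit(X8, Y8, tree8)
        grid = np.linspace(-1, 3, 9)
        _, lo95, hi95 = pgls_confband(fit, grid, level=0.95)
        _, lo99, hi99 = pgls_confband(fit, grid, level=0.99)
        assert np.all(lo99 < lo95) and np.all(hi99 > hi95)

    def test_bad_level(self, tree8):
        fit = pgls_fit(X8, Y8, tree8)
        with pytest.raises(InvalidArgumentError):
            pgls_confband(fit, [0.0], level=1.5)


class TestPredictNewTip:
    REF = "((A:1,B:1):1,(C:1,D:1):1);"
    WITH_TIP = "(((A:0.5,N:0.5):0.5,B:1):1,(C:1,D:1):1);"
    X4 = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("ABCD"))
    Y4 = pd.Series([1.1, 1.4, 2.2, 2.4], index=list("ABCD"))

    def test_independent_tip_reduces_to_fixed_effect(self):
        ref = read_newick(self.REF)
        split = read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,N:3);")
        fit = pgls_fit(self.X4, self.Y4, ref, lam=1.0)
        mean, var = pgls_predict_newtip(fit, split, "N", 1.5)
        x0 = np.array([1.0, 1.5])
        assert mean == pytest.approx(fit.predict(1.5), abs=1e-10)
        assert var == pytest.approx(fit.sigma2 + x0 @ fit.param_cov @ x0,
                                    abs=1e-10)

    def test_twin_limit_recovers_observed_value(self):
        ref = read_newick(self.REF)
        twin = read_newick(
            "(((A:0.000001,N:0.000001):0.999999,B:1):1,(C:1,D:1):1);")
        fit = pgls_fit(self.X4, self.Y4, ref, lam=1.0)
        mean, _ = pgls_predict_newtip(fit, twin, "N", float(self.X4["A"]))
        assert mean == pytest.approx(float(self.Y4["A"]), abs=1e-4)

    def test_matches_conditional_normal_oracle(self):
        """Dense-algebra oracle: conditional MVN mean/variance given the
        fitted parameters, plus the explicit parameter-uncertainty term."""
        ref = read_newick(self.REF)
        tree5 = read_newick(self.WITH_TIP)
        fit = pgls_fit(self.X4, self.Y4, ref, lam=1.0)
        x_new = 0.4
        mean, var = pgls_predict_newtip(fit, tree5, "N", x_new)

        # oracle correlations on the 5-taxon tree (depth 2):
        # N-A share 1.5/2, N-B share 1/2, N-C = N-D = 0
        lam = fit.lambda_hat
        order = list("ABCD")
        Crr = np.array(balanced4_corr(), dtype=float)
        Crr = lam * Crr
        np.fill_diagonal(Crr, 1.0)
        v = lam * np.array([0.75, 0.5, 0.0, 0.0])
        Ci = np.linalg.inv(Crr)
        X = np.column_stack([np.ones(4), self.X4[order].values])
        beta = np.array([fit.intercept, fit.slope])
        resid = self.Y4[order].values - X @ beta
        exp_mean = beta[0] + beta[1] * x_new + v @ Ci @ resid
        x0 = np.array([1.0, x_new])
        d = x0 - X.T @ Ci @ v
        exp_var = fit.sigma2 * (1 - v @ Ci @ v) + d @ fit.param_cov @ d
        assert mean == pytest.approx(exp_mean, abs=1e-8)
        assert var == pytest.approx(exp_var, abs=1e-8)

    def test_unknown_tip_rejected(self):
        ref = read_newick(self.REF)
        fit = pgls_fit(self.X4, self.Y4, ref, lam=1.0)
        with pytest.raises(InvalidArgumentError):
            pgls_predict_newtip(fit, ref, "Missing", 1.0)


def balanced4_corr():
    """Correlation of ((A,B),(C,D)) with depth 2: siblings share 1/2."""
    return [[1.0, 0.5, 0.0, 0.0],
            [0.5, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.5],
            [0.0, 0.0, 0.5, 1.0]]


def test_slope_ci_covers_truth_on_simulations():
    """95% CIs for the slope cover the generating value at roughly the
    nominal rate on lambda-Brownian simulations (40 quick replicates;
    the full 500-replicate calibration runs in the acceptance suite)."""
    from scipy.stats import norm
    from phenoceiling.synthetic_data import simulate_scaling_traits, simulate_tree

    z = norm.ppf(0.975)
    cover = 0
    n_rep = 40
    for i in range(n_rep):
        tr = simulate_tree(100, seed=500 + i)
        d = simulate_scaling_traits(tr, 2.0, -1.5, 0.5, 0.2, seed=900 + i)
        fit = pgls_fit(pd.Series(d["log10_mass"].values, index=d["species"]),
                       pd.Series(d["response"].values, index=d["species"]), tr)
        if abs(fit.slope + 1.5) <= z * np.sqrt(fit.param_cov[1, 1]):
            cover += 1
    assert 0.80 <= cover / n_rep <= 1.0
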