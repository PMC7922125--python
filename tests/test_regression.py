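"""Weighted least squares, Wald tests, and the three nested algorithms."""

import numpy as np
import pytest
from scipy import stats

from snpindep import (
    DegenerateDesignError,
    InvalidParameterError,
    SimulatedDataset,
    SimulationParams,
    algorithm0,
    algorithm1,
    algorithm2,
    fit_linear,
    simulate_dataset,
)


def wls_oracle(y, X, w=None):
    """Brute-force normal equations (X'WX)^-1 X'Wy with t-based p-values."""
    n, k = X.shape
    W = np.diag(np.ones(n) if w is None else np.asarray(w, float))
    XtWX_inv = np.linalg.inv(X.T @ W @ X)
    beta = XtWX_inv @ X.T @ W @ y
    resid = y - X @ beta
    df = n - k
    s2 = float(resid @ W @ resid) / df
    if w is not None:
        s2 *= n / np.sum(w)  # match sum(w)=n normalisation
        XtWX_inv = XtWX_inv / (n / np.sum(w))
    se = np.sqrt(s2 * np.diag(XtWX_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p


# fixed 8-observation dataset used for the frozen-oracle check
X8 = np.array(
    [
        [1, 0, 0, 0],
        [1, 1, 0, 0],
        [1, 0, 1, 0],
        [1, 1, 1, 1],
        [1, 0, 1, 0],
        [1, 1, 0, 0],
        [1, 1, 1, 1],
        [1, 0, 0, 0],
    ],
    dtype=float,
)
Y8 = np.array([0.12, 0.55, 0.31, 1.21, 0.27, 0.49, 1.02, -0.08])
W8 = np.array([1.0, 2.0, 1.0, 0.5, 1.5, 1.0, 2.0, 1.0])


class TestFitLinear:
    def test_perfect_line_is_exact_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        fit = fit_linear(y, X, term_names=["const", "x"])
        np.testing.assert_allclose(fit.coef, [1.0, 1.0], atol=1e-12)
        assert fit.exact_fit
        assert fit.sigma2_hat == 0.0
        assert fit["x"]["pvalue"] == 0.0

    def test_fixed_dataset_matches_normal_equations_oracle(self):
        fit = fit_linear(Y8, X8, weights=W8)
        beta, se, t, p = wls_oracle(Y8, X8, W8)
        np.testing.assert_allclose(fit.coef, beta, rtol=1e-8)
        np.testing.assert_allclose(fit.se, se, rtol=1e-8)
        np.testing.assert_allclose(fit.pvalue, p, rtol=1e-8)

    def test_weight_scale_invariance(self):
        f1 = fit_linear(Y8, X8, weights=W8)
        f2 = fit_linear(Y8, X8, weights=W8 * 73.5)
        np.testing.assert_allclose(f1.coef, f2.coef, rtol=1e-12)
        np.testing.assert_allclose(f1.se, f2.se, rtol=1e-12)
        np.testing.assert_allclose(f1.pvalue, f2.pvalue, rtol=1e-12)

    def test_agrees_with_statsmodels_wls(self, rng):
        """Independent cross-check against an external WLS implementation."""
        import statsmodels.api as sm

        n, k = 60, 4
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = X @ rng.normal(size=k) + rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, n)
        fit = fit_linear(y, X, weights=w)
        ref = sm.WLS(y, X, weights=w).fit()
        np.testing.assert_allclose(fit.coef, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.pvalue, ref.pvalues, rtol=1e-8)
        assert fit.df_resid == ref.df_resid

    def test_random_small_designs_match_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(8, 21))
            k = int(rng.integers(2, 6))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = rng.normal(size=n)
            fit = fit_linear(y, X)
            beta, se, t, p = wls_oracle(y, X)
            np.testing.assert_allclose(fit.coef, beta, rtol=1e-8)
            np.testing.assert_allclose(fit.se, se, rtol=1e-8)

    def test_aliased_column_dropped_and_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        fit = fit_linear(rng.normal(size=30), X, term_names=["const", "a", "b"])
        assert fit.rank_deficient
        assert fit.aliased.sum() == 1
        assert not fit.aliased[0]  # intercept always survives
        assert np.isnan(fit.coef[fit.aliased]).all()

    def test_df_resid_equals_n_minus_rank(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        X = np.column_stack([np.ones(12), x, x])
        fit = fit_linear(rng.normal(size=12), X)
        assert fit.df_resid == 12 - 2

    def test_degenerate_design_raises(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear(np.array([1.0, 2.0]), np.column_stack([np.ones(2), [0.0, 1.0]]))
        with pytest.raises(InvalidParameterError):
            fit_linear(np.array([]), np.empty((0, 1)))

    def test_bad_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_linear(Y8, X8, weights=np.zeros(8))
        with pytest.raises(InvalidParameterError):
            fit_linear(Y8, X8, weights=-W8)

    def test_pvalues_in_unit_interval_random_designs(self):
        """Seeded property check: p in [0,1], se > 0 on estimable terms."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(6, 16))
            k = int(rng.integers(1, 5))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
            y = rng.normal(size=n)
            fit = fit_linear(y, X)
            ok = ~fit.aliased
            assert np.all((fit.pvalue[ok] >= 0) & (fit.pvalue[ok] <= 1))
            assert np.all(fit.se[ok] > 0) or fit.exact_fit
            assert fit.df_resid == n - (~fit.aliased).sum()


def _dataset(x1, x2, y):
    return SimulatedDataset(x1=np.asarray(x1), x2=np.asarray(x2), y=np.asarray(y, float))


class TestAlgorithms:
    def test_constant_x1_fails_algorithm0(self):
        d = _dataset(np.ones(20), np.arange(20) % 2, np.random.default_rng(0).normal(size=20))
        res = algorithm0(d)
        assert res.failed
        assert np.isnan(res.p_target)

    def test_exact_fit_reports_zero_pvalue(self):
        x1 = np.array([0, 1] * 10)
        d = _dataset(x1, np.zeros(20), 0.3 * x1)
        res = algorithm0(d)
        assert not res.failed
        assert res.p_target == 0.0
        assert res.fit.exact_fit

    def test_perfect_collinearity_fails_algorithm1(self, rng):
        x = (rng.random(50) < 0.5).astype(int)
        d = _dataset(x, x, rng.normal(size=50))
        res = algorithm1(d)
        assert res.failed
        assert res.fit.rank_deficient

    def test_zero_interaction_contrast_fails_algorithm2(self, rng):
        x1 = (rng.random(50) < 0.5).astype(int)
        d = _dataset(x1, np.zeros(50), rng.normal(size=50))
        res = algorithm2(d)
        assert res.failed

    def test_exact_signal_rejects_conditional(self, rng):
        x1 = (rng.random(40) < 0.5).astype(int)
        x2 = (rng.random(40) < 0.5).astype(int)
        d = _dataset(x1, x2, x1.astype(float))
        res = algorithm1(d)
        assert res.p_target == 0.0

    def test_conditional_null_pvalues_uniform(self):
        """Y generated from X2 only: Algorithm 1's p for X1 is U(0,1)."""
        root = np.random.SeedSequence(17)
        ps = []
        for child in root.spawn(500):
            rng = np.random.default_rng(child)
            x1 = (rng.random(400) < 0.5).astype(int)
            x2 = (rng.random(400) < 0.5).astype(int)
            y = 0.5 * x2 + rng.normal(size=400)
            ps.append(algorithm1(_dataset(x1, x2, y)).p_target)
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_interaction_null_pvalues_uniform(self):
        """beta_I = 0 generation: Algorithm 2's interaction p is U(0,1)."""
        root = np.random.SeedSequence(23)
        ps = []
        for child in root.spawn(500):
            rng = np.random.default_rng(child)
            d = simulate_dataset(SimulationParams(n=400, beta_I=0.0), rng=rng)
            ps.append(algorithm2(d).p_target)
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_strong_effects_detected_at_genomewide_level(self):
        """beta_I = 1 at n=1000: all three nulls rejected in most replicates."""
        root = np.random.SeedSequence(31)
        hits = np.zeros(3)
        nrep = 100
        for child in root.spawn(nrep):
            rng = np.random.default_rng(child)
            d = simulate_dataset(SimulationParams(beta_I=1.0), rng=rng)
            for j, alg in enumerate((algorithm0, algorithm1, algorithm2)):
                hits[j] += alg(d).p_target < 5e-8
        assert (hits / nrep > 0.5).all()

    def test_covariate_adjustment_changes_design(self, rng):
        d = simulate_dataset(SimulationParams(n=300, seed=8))
        cov = rng.normal(size=(300, 2))
        res = algorithm1(d, covariates=cov)
        assert len(res.fit.term_names) == 5
        assert not res.failed
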