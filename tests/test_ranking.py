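"""Ridge closed forms, error decomposition, heritability scores, ranking."""

import numpy as np
import pytest
from scipy.optimize import minimize

import stableselect as ss
from stableselect.ranking import DesignMatrix


def random_instance(rng, n=20, p=5, heteroscedastic=False):
    X = rng.standard_normal((n, p))
    X[:, 0] = 1.0
    delta = rng.uniform(0.5, 2.0, n) if heteroscedastic else np.ones(n)
    y = rng.standard_normal(n)
    return DesignMatrix(X=X, delta=delta), y


class TestRidgeFit:
    def test_identity_design_halves_y(self):
        D = DesignMatrix(X=np.eye(3), delta=np.ones(3), has_intercept=False)
        fit = ss.ridge_fit(D, np.array([1.0, 2.0, 3.0]), C=1.0)
        np.testing.assert_allclose(fit.m_bar, [0.5, 1.0, 1.5])
        # ||y||^2 = 14, explained 3.5, penalty 3.5 -> residual 7
        assert fit.e_res2 == pytest.approx(7.0)

    @pytest.mark.parametrize("heteroscedastic", [False, True])
    def test_closed_form_matches_numerical_minimizer(self, rng, heteroscedastic):
        for _ in range(5):
            D, y = random_instance(rng, n=20, p=5, heteroscedastic=heteroscedastic)
            C = float(rng.uniform(0.1, 5.0))
            fit = ss.ridge_fit(D, y, C)
            res = minimize(
                lambda m: ss.weighted_objective(D, y, C, m),
                np.zeros(5),
                method="BFGS",
                options={"gtol": 1e-12, "maxiter": 2000},
            )
            np.testing.assert_allclose(fit.m_bar, res.x, atol=1e-6)
            assert fit.e_res2 <= res.fun + 1e-10

    def test_conservation_identity(self, rng):
        for _ in range(10):
            D, y = random_instance(rng, n=25, p=8, heteroscedastic=True)
            fit = ss.ridge_fit(D, y, C=0.7)
            total = fit.e_res2 + fit.explained + fit.penalty
            assert total == pytest.approx(fit.total_weighted_ss, rel=1e-10)
            assert fit.e_res2 >= -1e-10

    def test_ols_limit(self, rng):
        D, y = random_instance(rng, n=30, p=6)
        fit = ss.ridge_fit(D, y, C=1e-10)
        ols, *_ = np.linalg.lstsq(D.X, y, rcond=None)
        np.testing.assert_allclose(fit.m_bar, ols, atol=1e-6)

    def test_dual_and_primal_agree(self, rng):
        # p > n triggers the dual path; compare against explicit normal equations
        X = rng.standard_normal((10, 25))
        D = DesignMatrix(X=X, delta=np.ones(10), has_intercept=False)
        y = rng.standard_normal(10)
        fit = ss.ridge_fit(D, y, C=2.0)
        direct = np.linalg.solve(X.T @ X + 2.0 * np.eye(25), X.T @ y)
        np.testing.assert_allclose(fit.m_bar, direct, atol=1e-8)

    def test_shrinkage_monotone_in_C(self, rng):
        D, y = random_instance(rng, n=30, p=6)
        norms = [np.linalg.norm(ss.ridge_fit(D, y, C).m_bar) for C in (0.1, 1, 10, 100, 1000)]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_singular_needs_positive_C(self):
        X = np.ones((4, 2))  # rank 1
        D = DesignMatrix(X=X, delta=np.ones(4), has_intercept=False)
        with pytest.raises(ValueError, match="C"):
            ss.ridge_fit(D, np.ones(4), C=0.0)

    def test_cov_sandwich_matches_naive_algebra(self, rng):
        D, y = random_instance(rng, n=15, p=4, heteroscedastic=True)
        fit = ss.ridge_fit(D, y, C=0.9)
        W = np.diag(D.delta**-2)
        gram = D.X.T @ W @ D.X
        A_inv = np.linalg.inv(gram + 0.9 * np.eye(4))
        np.testing.assert_allclose(fit.cov_m, A_inv @ gram @ A_inv, atol=1e-10)
        evals = np.linalg.eigvalsh(fit.cov_m)
        assert evals.min() > -1e-12  # PSD


class TestErrorDecomposition:
    def test_identity_holds_for_random_m(self, rng):
        D, y = random_instance(rng, n=30, p=10, heteroscedastic=True)
        fit = ss.ridge_fit(D, y, C=1.3)
        scale = fit.total_weighted_ss
        for _ in range(100):
            m = rng.standard_normal(10) * rng.uniform(0.1, 10)
            assert ss.error_decomposition_check(D, y, fit, m) < 1e-10 * scale

    def test_minimum_attained_at_m_bar(self, rng):
        D, y = random_instance(rng, n=12, p=4)
        fit = ss.ridge_fit(D, y, C=0.5)
        assert ss.weighted_objective(D, y, 0.5, fit.m_bar) == pytest.approx(fit.e_res2)


class TestHeritability:
    def test_zero_coefficients_zero_scores(self, rng):
        D, _ = random_instance(rng, n=10, p=4)
        fit = ss.ridge_fit(D, np.zeros(10), C=1.0)
        h = ss.feature_heritability(D, fit)
        np.testing.assert_allclose(h.h, 0.0, atol=1e-20)

    def test_orthonormal_columns_sum_to_explained(self, rng):
        # orthonormal X, delta = I: h_j = m_j^2 and sum h_j = ||X m||^2
        Q, _ = np.linalg.qr(rng.standard_normal((20, 5)))
        D = DesignMatrix(X=Q, delta=np.ones(20), has_intercept=False)
        y = rng.standard_normal(20)
        fit = ss.ridge_fit(D, y, C=0.8)
        h = ss.feature_heritability(D, fit)
        np.testing.assert_allclose(h.h, fit.m_bar**2, atol=1e-12)
        assert h.h.sum() == pytest.approx(np.sum((Q @ fit.m_bar) ** 2), rel=1e-10)

    def test_correlated_columns_gap_equals_cross_term(self, rng):
        x1 = rng.standard_normal(30)
        x2 = 0.7 * x1 + 0.3 * rng.standard_normal(30)
        X = np.column_stack([x1, x2])
        D = DesignMatrix(X=X, delta=np.ones(30), has_intercept=False)
        y = x1 + rng.standard_normal(30)
        fit = ss.ridge_fit(D, y, C=0.4)
        h = ss.feature_heritability(D, fit)
        explained = fit.explained
        m = fit.m_bar
        cross = 2.0 * m[0] * m[1] * float(x1 @ x2)
        assert explained - h.h.sum() == pytest.approx(cross, rel=1e-10)
        # cross-term variant recovers the full explained sum
        h_full = ss.feature_heritability(D, fit, include_cross_terms=True)
        assert h_full.h.sum() == pytest.approx(explained, rel=1e-10)

    def test_intercept_excluded_from_ranking(self, small_cohort):
        G, P, _ = small_cohort
        D = ss.build_design(G)
        fit = ss.ridge_fit(D, P.status, C=1.0)
        h = ss.feature_heritability(D, fit)
        assert len(h.h) == G.n_snps
        assert h.feature_names[0] != "_intercept"


class TestRankFeatures:
    def test_example_order(self):
        rk = ss.rank_features(np.array([0.1, 0.5, 0.3]))
        np.testing.assert_array_equal(rk.order, [1, 2, 0])

    def test_all_equal_keeps_original_order(self):
        rk = ss.rank_features(np.array([0.2, 0.2, 0.2, 0.2]))
        np.testing.assert_array_equal(rk.order, np.arange(4))
        np.testing.assert_array_equal(rk.sigma, np.arange(4))

    def test_matches_decorate_sort_oracle(self, rng):
        h = rng.random(40)
        rk = ss.rank_features(h)
        oracle = [j for _, j in sorted(((-h[j], j) for j in range(40)))]
        np.testing.assert_array_equal(rk.order, oracle)
        assert sorted(rk.sigma) == list(range(40))  # bijection

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            ss.rank_features(np.array([0.1, np.nan]))


class TestRankByFolds:
    def test_deterministic_under_seed(self, small_cohort):
        G, P, _ = small_cohort
        a = ss.rank_by_folds(G, P.status, 3, 0.2, 1.0, rng=7)
        b = ss.rank_by_folds(G, P.status, 3, 0.2, 1.0, rng=7)
        np.testing.assert_array_equal(a.order, b.order)

    def test_recovers_planted_strong_causal(self):
        hits = 0
        for seed in range(20):
            cfg = ss.SimulationConfig(
                n_samples=500, n_snps=200, causal_indices=(0,),
                causal_betas=(float(np.log(3.0)),), rng_seed=seed,
            )
            G, P, _ = ss.simulate_cohort(cfg)
            rk = ss.rank_by_folds(G, P.status, 3, 0.2, C=200.0, rng=seed)
            hits += int(rk.order[0] == 0)
        assert hits >= 19  # causal ranked first in >= 95% of runs

    def test_fold_missing_class_errors(self, small_cohort):
        G, _, _ = small_cohort
        y = np.zeros(G.n_samples, dtype=int)
        with pytest.raises(ValueError):
            ss.rank_by_folds(G, y, 2, 0.2, 1.0, rng=0)
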