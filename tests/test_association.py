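"""Per-SNP association inference, predictivity scoring, PRS weight rule."""

import numpy as np
import pytest
from scipy import stats

import stableselect as ss


class TestContingencyOrTest:
    def test_symmetric_table_is_null(self):
        a = ss.contingency_or_test(ss.ContingencyTable(10, 10, 10, 10))
        assert a.odds_ratio == pytest.approx(1.0)
        assert a.p_value == pytest.approx(1.0)

    def test_hand_computed_example_against_normal_cdf(self):
        a = ss.contingency_or_test(ss.ContingencyTable(20, 20, 5, 5))
        assert a.odds_ratio == pytest.approx(16.0)
        assert a.se_log_or == pytest.approx(np.sqrt(0.5), rel=1e-12)
        z = np.log(16.0) / np.sqrt(0.5)
        assert z == pytest.approx(3.921, abs=1e-3)
        assert a.p_value == pytest.approx(2 * stats.norm.sf(z), rel=1e-10)

    def test_zero_cell_haldane_correction(self):
        a = ss.contingency_or_test(ss.ContingencyTable(10, 10, 0, 5))
        assert a.zero_cell_corrected
        expected_or = (10.5 * 10.5) / (0.5 * 5.5)
        assert a.odds_ratio == pytest.approx(expected_or)

    def test_double_swap_invariance_and_exposure_inversion(self):
        t = ss.ContingencyTable(12, 30, 7, 19)
        a = ss.contingency_or_test(t)
        swapped = ss.contingency_or_test(ss.ContingencyTable(30, 12, 19, 7))
        assert swapped.odds_ratio == pytest.approx(a.odds_ratio)
        assert swapped.p_value == pytest.approx(a.p_value)
        inverted = ss.contingency_or_test(ss.ContingencyTable(7, 19, 12, 30))
        assert inverted.odds_ratio == pytest.approx(1.0 / a.odds_ratio)
        assert inverted.p_value == pytest.approx(a.p_value)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ss.ContingencyTable(-1, 5, 5, 5)


class TestLogisticAssoc:
    def test_constant_dosage_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ss.logistic_assoc(np.ones(50), np.array([0, 1] * 25))

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(31)
        pvals = []
        for _ in range(300):
            g = rng.integers(0, 3, 300).astype(float)
            y = rng.integers(0, 2, 300)
            a = ss.logistic_assoc(g, y)
            if a.converged:
                pvals.append(a.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(77)
        n_sims, hits, used = 2000, 0, 0
        for _ in range(n_sims):
            g = rng.integers(0, 3, 1000).astype(float)
            y = rng.integers(0, 2, 1000)
            a = ss.logistic_assoc(g, y)
            if a.converged:
                used += 1
                hits += int(a.p_value < 0.05)
        assert 0.035 <= hits / used <= 0.065

    def test_agrees_with_contingency_on_binary_exposure(self):
        rng = np.random.default_rng(5)
        n = 4000
        e = rng.integers(0, 2, n)
        p_case = np.where(e == 1, 0.6, 0.4)
        y = (rng.random(n) < p_case).astype(int)
        logit = ss.logistic_assoc(e.astype(float), y)
        t = ss.ContingencyTable(
            n_DE=int(((y == 1) & (e == 1)).sum()),
            n_de=int(((y == 0) & (e == 0)).sum()),
            n_De=int(((y == 1) & (e == 0)).sum()),
            n_dE=int(((y == 0) & (e == 1)).sum()),
        )
        cont = ss.contingency_or_test(t)
        assert logit.log_or == pytest.approx(cont.log_or, rel=0.1)
        assert logit.se_log_or == pytest.approx(cont.se_log_or, rel=0.1)

    def test_complete_separation_flagged(self):
        g = np.array([0.0] * 20 + [2.0] * 20)
        y = np.array([0] * 20 + [1] * 20)
        a = ss.logistic_assoc(g, y)
        assert not a.converged
        assert np.isnan(a.p_value)


class TestEvaluatePredictivity:
    def test_perfect_feature_perfect_f1(self):
        y = np.array([0, 1] * 40)
        rep = ss.evaluate_predictivity(y.astype(float) * 2, y, m_folds=3, t_test=0.25, rng=0)
        assert rep.f1 == pytest.approx(1.0)
        assert rep.auc == pytest.approx(1.0)

    def test_f1_is_harmonic_mean_of_precision_recall(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((200, 3))
        beta = np.array([1.0, 0.5, 0.0])
        y = (X @ beta + rng.standard_normal(200) > 0).astype(int)
        rep = ss.evaluate_predictivity(X, y, m_folds=1, t_test=0.3, rng=4)
        hm = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
        assert rep.f1 == pytest.approx(hm, rel=1e-10)

    def test_noise_features_on_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(21)
        n = 500
        X = rng.standard_normal((n, 10))
        y = rng.permutation(np.array([0, 1] * (n // 2)))
        rep = ss.evaluate_predictivity(X, y, m_folds=5, t_test=0.25, rng=8)
        # chance F1 for a balanced cohort is ~0.5; allow a generous band
        assert 0.3 < rep.f1 < 0.65
        assert 0.35 < rep.auc < 0.65

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            ss.evaluate_predictivity(np.empty((10, 0)), np.array([0, 1] * 5), 2, 0.3, 0)


class TestSubsetBySignificance:
    def test_filter_matches_brute_force(self):
        results = [
            ss.AssociationResult(f"s{i}", 1.0, 0.0, 1.0, p, "contingency")
            for i, p in enumerate([1e-31, 1e-29, 0.5, 1e-45])
        ]
        got = ss.subset_by_significance(results, 30.0)
        expected = {r.snp_id for r in results if r.p_value < 1e-30}
        assert got == expected

    def test_zero_threshold_takes_everything_below_one(self):
        results = [
            ss.AssociationResult("a", 1.0, 0.0, 1.0, 0.9, "contingency"),
            ss.AssociationResult("b", 1.0, 0.0, 1.0, 1.0, "contingency"),
        ]
        assert ss.subset_by_significance(results, 0.0) == {"a"}


class TestBetaHistogram:
    def test_spike_plus_outliers_selects_exactly_outliers(self):
        rng = np.random.default_rng(12)
        n = 100_000
        beta = np.concatenate([rng.normal(0.0, 1e-5, n - 10), np.full(10, 0.5)])
        ids = tuple(f"w{i}" for i in range(n))
        w = ss.PRSWeights(snp_ids=ids, beta=beta)
        got = ss.select_by_beta_histogram(w, n_bins=50, bin_fraction_max=2e-4)
        assert got == {f"w{i}" for i in range(n - 10, n)}

    def test_uniform_betas_select_nothing(self):
        rng = np.random.default_rng(13)
        w = ss.PRSWeights(
            snp_ids=tuple(f"u{i}" for i in range(1000)), beta=rng.uniform(-1, 1, 1000)
        )
        assert ss.select_by_beta_histogram(w, 50, 2e-4) == set()

    def test_identical_betas_select_nothing(self):
        w = ss.PRSWeights(snp_ids=("a", "b", "c"), beta=np.full(3, 0.2))
        assert ss.select_by_beta_histogram(w) == set()

    def test_empty_input_errors(self):
        w = ss.PRSWeights(snp_ids=(), beta=np.array([]))
        with pytest.raises(ValueError):
            ss.select_by_beta_histogram(w)

    def test_magnitude_rule_alternative(self):
        w = ss.PRSWeights(snp_ids=("a", "b", "c"), beta=np.array([1e-5, 3e-4, -0.01]))
        assert ss.select_by_beta_magnitude(w, 2e-4) == {"b", "c"}
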