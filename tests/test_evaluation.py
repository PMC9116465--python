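"""SROCC / logistic remapping / PLCC / RMSE, repeated-split evaluation
and the corrected resampled paired t-test."""

import numpy as np
import pytest
from scipy import stats

import oracles
from ceiqa import (
    GridSearchSpec,
    corrected_resampled_ttest,
    logistic_fit,
    plcc_rmse,
    repeated_split_eval,
    significance_matrix,
    srocc,
)
from ceiqa.evaluation import corrected_t_statistic, split_indices
from ceiqa.exceptions import DataError, ParameterError

SMALL_SPEC = GridSearchSpec(c_grid=(1.0, 64.0), gamma_grid=(2**-6, 2**-2), cv=3)


class TestSROCC:
    def test_identical_vectors(self):
        assert srocc([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed_ranking(self):
        assert srocc([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_one_swap_gives_point_nine(self):
        assert srocc([1, 2, 3, 5, 4], [1, 2, 3, 4, 5]) == pytest.approx(0.9)

    def test_matches_rank_pearson_oracle_with_ties(self, rng):
        for _ in range(20):
            a = rng.integers(0, 6, size=15).astype(float)  # many ties
            b = rng.integers(0, 6, size=15).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            assert srocc(a, b) == pytest.approx(oracles.spearman(a, b), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError):
            srocc([1, 1, 1], [1, 2, 3])


class TestLogisticFit:
    def test_identity_relation_zero_residual(self, rng):
        x = rng.uniform(1, 5, size=30)
        fit = logistic_fit(x, x)
        assert fit.converged
        np.testing.assert_allclose(fit(x), x, atol=1e-5)

    def test_affine_relation_zero_residual(self, rng):
        x = rng.uniform(1, 5, size=30)
        fit = logistic_fit(x, 2.0 * x + 1.0)
        np.testing.assert_allclose(fit(x), 2.0 * x + 1.0, atol=1e-5)

    def test_recovers_generating_sigmoid(self, rng):
        beta = (2.0, 3.0, 2.5, 0.5, 3.0)
        x = rng.uniform(0, 5, size=200)
        from ceiqa.evaluation import _logistic5

        y = _logistic5(x, *beta)
        fit = logistic_fit(x, y)
        np.testing.assert_allclose(fit(x), y, atol=1e-4)

    def test_constant_predictions_rejected(self):
        with pytest.raises(DataError):
            logistic_fit(np.ones(10), np.arange(10.0))


class TestPLCCRMSE:
    def test_perfect_prediction(self, rng):
        x = rng.uniform(1, 5, size=40)
        plcc, rmse = plcc_rmse(x, x)
        assert plcc == pytest.approx(1.0, abs=1e-6)
        assert rmse == pytest.approx(0.0, abs=1e-5)

    def test_negated_prediction_absorbed_by_fit(self, rng):
        x = rng.uniform(1, 5, size=40)
        plcc, rmse = plcc_rmse(-x, x)
        assert plcc == pytest.approx(1.0, abs=1e-6)
        assert rmse == pytest.approx(0.0, abs=1e-5)

    def test_pure_noise_gives_small_plcc(self, rng):
        pred = rng.normal(size=1000)
        mos = rng.normal(size=1000)
        plcc, _ = plcc_rmse(pred, mos)
        assert abs(plcc) < 0.15

    def test_noise_degrades_all_three_criteria(self, rng):
        """Adding prediction noise lowers SROCC/PLCC and raises RMSE on
        average — the criteria move together."""
        mos = rng.uniform(1, 5, size=80)
        results = []
        for sigma in (0.0, 0.5, 2.0):
            sr = pl = rm = 0.0
            for rep in range(5):
                pred = mos + rng.normal(0, sigma, size=80)
                sr += srocc(pred, mos)
                p, r = plcc_rmse(pred, mos)
                pl += p
                rm += r
            results.append((sr / 5, pl / 5, rm / 5))
        assert results[0][0] > results[1][0] > results[2][0]
        assert results[0][1] > results[1][1] > results[2][1]
        assert results[0][2] < results[1][2] < results[2][2]


class TestSplits:
    def test_round_policy_on_642(self):
        splits = split_indices(642, 1, 0.8, seed=0)
        assert len(splits[0][0]) == 514  # round(0.8 * 642)
        assert len(splits[0][1]) == 128

    def test_partitions_are_disjoint_and_cover(self):
        tr, te = split_indices(50, 1, 0.8, seed=1)[0]
        assert len(np.intersect1d(tr, te)) == 0
        assert len(np.union1d(tr, te)) == 50

    def test_seed_replay(self):
        s1 = split_indices(100, 5, 0.8, seed=9)
        s2 = split_indices(100, 5, 0.8, seed=9)
        for (a, b), (c, d) in zip(s1, s2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ParameterError):
            split_indices(10, 1, 1.5, seed=0)


@pytest.fixture(scope="module")
def easy_features():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 1, size=(60, 6))
    y = 1.0 + 4.0 * X[:, 0] + rng.normal(0, 0.2, size=60)
    return X, np.clip(y, 1, 5)


class TestRepeatedEval:
    def test_summary_consistency_and_determinism(self, easy_features):
        X, y = easy_features
        s1 = repeated_split_eval(X, y, n_repeats=3, seed=5, model_spec=SMALL_SPEC)
        s2 = repeated_split_eval(X, y, n_repeats=3, seed=5, model_spec=SMALL_SPEC)
        np.testing.assert_array_equal(s1.srocc, s2.srocc)
        np.testing.assert_array_equal(s1.rmse, s2.rmse)
        assert s1.median_srocc == np.median(s1.srocc)
        assert s1.std_srocc == pytest.approx(np.std(s1.srocc, ddof=1))
        assert s1.n_train == 48 and s1.n_test == 12
        assert len(s1.to_frame()) == 3

    def test_criteria_in_valid_ranges(self, easy_features):
        X, y = easy_features
        s = repeated_split_eval(X, y, n_repeats=3, seed=1, model_spec=SMALL_SPEC)
        assert np.all(np.abs(s.srocc) <= 1.0)
        assert np.all(np.abs(s.plcc) <= 1.0)
        assert np.all(s.rmse >= 0.0)


class TestCorrectedTTest:
    def test_identical_scores_similar(self):
        a = np.array([0.8, 0.82, 0.81, 0.83])
        assert corrected_resampled_ttest(a, a, 80, 20) == 0

    def test_antisymmetry(self, rng):
        for _ in range(10):
            a = rng.normal(0.8, 0.05, size=12)
            b = rng.normal(0.7, 0.05, size=12)
            d1 = corrected_resampled_ttest(a, b, 80, 20)
            d2 = corrected_resampled_ttest(b, a, 80, 20)
            assert d1 == -d2

    def test_statistic_matches_scalar_oracle(self, rng):
        d = 0.05 + rng.normal(0, 0.001, size=10)
        t_impl = corrected_t_statistic(d, n_train=80, n_test=20)
        t_oracle = oracles.corrected_t(d, 80, 20)
        assert t_impl == pytest.approx(t_oracle, rel=1e-12)
        # decision agrees with direct evaluation of the oracle statistic
        crit = stats.t.ppf(0.975, df=9)
        expect = 1 if t_oracle > crit else (-1 if t_oracle < -crit else 0)
        assert corrected_resampled_ttest(d + 0.0, np.zeros(10), 80, 20) == expect

    def test_correction_shrinks_the_statistic(self, rng):
        d = rng.normal(0.02, 0.01, size=15)
        t_corr = corrected_t_statistic(d, 80, 20)
        t_plain = stats.ttest_1samp(d, 0.0).statistic
        assert abs(t_corr) <= abs(t_plain)

    def test_clear_difference_detected(self):
        a = np.full(20, 0.85) + np.linspace(-0.01, 0.01, 20)
        b = np.full(20, 0.55) + np.linspace(-0.01, 0.01, 20)
        assert corrected_resampled_ttest(a, b, 80, 20) == 1


class TestSignificanceMatrix:
    def test_identical_methods_all_zero(self):
        a = np.array([0.8, 0.81, 0.79, 0.8])
        mat = significance_matrix({"m1": a, "m2": a.copy()}, 80, 20)
        assert (mat.to_numpy() == 0).all()

    def test_antisymmetric_with_zero_diagonal(self, rng):
        scores = {f"m{i}": rng.normal(0.7 + 0.05 * i, 0.02, size=10)
                  for i in range(4)}
        mat = significance_matrix(scores, 80, 20).to_numpy()
        np.testing.assert_array_equal(mat, -mat.T)
        np.testing.assert_array_equal(np.diag(mat), 0)

    def test_transitive_dominance_pattern(self):
        jitter = np.linspace(-0.005, 0.005, 16)
        scores = {
            "a": 0.9 + jitter, "b": 0.7 + jitter, "c": 0.5 + jitter,
        }
        mat = significance_matrix(scores, 80, 20)
        assert mat.loc["a", "b"] == 1
        assert mat.loc["a", "c"] == 1
        assert mat.loc["b", "c"] == 1
        assert mat.loc["c", "a"] == -1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DataError):
            significance_matrix({"a": np.ones(5), "b": np.ones(6)}, 80, 20)
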