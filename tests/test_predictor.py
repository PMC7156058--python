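"""Splitting, correlation-filter probe selection and the PLSR fit."""

import numpy as np
import pytest
from scipy import stats

from splicerail.predictor import (
    PredictorConfig,
    PredictorModel,
    correlation_scores,
    fit,
    predict,
    select_probes,
    split_participants,
)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(27, (18, 9)), (10, (7, 3)), (36, (25, 11))])
    def test_split_sizes_floor_rule(self, n, expected, rng):
        ids = [f"p{i}" for i in range(n)]
        train, test = split_participants(ids, 0.7, rng)
        assert (len(train), len(test)) == expected

    @pytest.mark.parametrize("n", [5, 12, 27])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_property(self, n, seed):
        ids = [f"p{i}" for i in range(n)]
        rng = np.random.default_rng(seed)
        train, test = split_participants(ids, 0.7, rng)
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    def test_too_few_participants_rejected(self, rng):
        with pytest.raises(ValueError):
            split_participants(["a", "b"], 0.7, rng)

    def test_deterministic_given_rng_state(self):
        ids = [f"p{i}" for i in range(20)]
        a = split_participants(ids, 0.7, np.random.default_rng(42))
        b = split_participants(ids, 0.7, np.random.default_rng(42))
        assert a == b


class TestSelectProbes:
    def test_brute_force_pearson_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 5))
        y = rng.normal(size=6)
        expected_r = [stats.pearsonr(X[:, j], y).statistic for j in range(5)]
        order = sorted(range(5), key=lambda j: (-abs(expected_r[j]), j))
        np.testing.assert_array_equal(select_probes(X, y, 3), order[:3])
        np.testing.assert_allclose(correlation_scores(X, y), expected_r, rtol=1e-12)

    def test_k_exceeding_probe_count_returns_all_sorted(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        sel = select_probes(X, y, 100)
        assert len(sel) == 4
        r = np.abs(correlation_scores(X, y))
        assert list(r[sel]) == sorted(r, reverse=True)

    def test_perfect_probe_ranked_first(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(7, 6))
        y = rng.normal(size=7)
        X[:, 4] = y
        sel = select_probes(X, y, 2)
        assert sel[0] == 4
        assert abs(correlation_scores(X, y)[4]) == pytest.approx(1.0)

    def test_zero_variance_probe_scores_zero(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(6, 3))
        X[:, 1] = 7.0
        y = rng.normal(size=6)
        assert correlation_scores(X, y)[1] == 0.0

    def test_constant_response_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="constant"):
            select_probes(X, np.full(6, 3.0), 2)

    def test_spearman_metric_available(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        r = correlation_scores(X, y, metric="spearman")
        expected = [stats.spearmanr(X[:, j], y).statistic for j in range(3)]
        np.testing.assert_allclose(r, expected, rtol=1e-12)


class TestPLSRFit:
    def test_single_proportional_feature_recovers_exactly(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=8)
        X = (3.5 * y).reshape(-1, 1)
        model = fit(X, y, PredictorConfig(n_components=1))
        np.testing.assert_allclose(predict(model, X), y, atol=1e-10)

    def test_constant_response_gives_zero_coefficients(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(6, 4))
        y = np.full(6, 42.0)
        model = fit(X, y, PredictorConfig(n_components=2))
        np.testing.assert_allclose(model.coef, 0.0)
        np.testing.assert_allclose(predict(model, X), 42.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_nipals_on_random_problems(self, seed):
        """Cross-check against scikit-learn's independently written NIPALS."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        model = fit(X, y, PredictorConfig(n_components=2))
        reference = PLSRegression(n_components=2, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(
            predict(model, X), reference.predict(X).ravel(), atol=1e-8
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_full_components_equals_ols(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = fit(X, y, PredictorConfig(n_components=4))
        design = np.column_stack([np.ones(12), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(predict(model, X), design @ beta, atol=1e-8)

    def test_rank_deficiency_reduces_components(self, caplog):
        rng = np.random.default_rng(15)
        base = rng.normal(size=(6, 1))
        X = np.hstack([base, base, base])  # rank 1
        y = base.ravel() * 2
        model = fit(X, y, PredictorConfig(n_components=3))
        assert model.n_components_used < 3
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)

    def test_too_few_training_rows_rejected(self):
        X = np.zeros((2, 3))
        with pytest.raises(ValueError, match="n_components"):
            fit(X, np.array([1.0, 2.0]), PredictorConfig(n_components=2))


class TestPredict:
    def test_feature_mean_maps_to_response_mean(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        model = fit(X, y, PredictorConfig(n_components=2))
        at_mean = predict(model, X.mean(axis=0, keepdims=True))
        assert at_mean[0] == pytest.approx(y.mean())

    def test_affine_shift_moves_prediction_by_coefficient(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        model = fit(X, y, PredictorConfig(n_components=2))
        shifted = X.copy()
        shifted[:, 2] += 1.7
        np.testing.assert_allclose(
            predict(model, shifted) - predict(model, X),
            1.7 * model.coef[2],
            atol=1e-10,
        )

    def test_missing_selected_probe_rejected(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = fit(X, y, PredictorConfig(n_components=1), probe_ids=["a", "b", "c"])
        with pytest.raises(KeyError, match="b"):
            predict(model, X[:, [0, 2]], probe_ids=["a", "c"])

    def test_probe_id_reordering_handled(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = fit(X, y, PredictorConfig(n_components=1), probe_ids=["a", "b", "c"])
        reordered = predict(model, X[:, [2, 0, 1]], probe_ids=["c", "a", "b"])
        np.testing.assert_allclose(reordered, predict(model, X), atol=1e-12)


class TestInvariance:
    def test_select_then_fit_invariant_to_probe_order(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        cfg = PredictorConfig(n_components=2)

        sel = select_probes(X, y, 4)
        model = fit(X[:, sel], y, cfg)
        baseline = predict(model, X[:, sel])

        perm = np.random.default_rng(21).permutation(8)
        Xp = X[:, perm]
        sel_p = select_probes(Xp, y, 4)
        model_p = fit(Xp[:, sel_p], y, cfg)
        np.testing.assert_allclose(predict(model_p, Xp[:, sel_p]), baseline, atol=1e-10)

    def test_selection_ignores_test_rows(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        train = np.arange(14)
        sel = select_probes(X[train], y[train], 3)
        corrupted = X.copy()
        corrupted[14:] = 1e6 * rng.normal(size=(6, 6))
        sel_after = select_probes(corrupted[train], y[train], 3)
        np.testing.assert_array_equal(sel, sel_after)


class TestComparators:
    @pytest.mark.parametrize("kind", ["lasso", "linear", "random_forest"])
    def test_comparators_fit_strong_signal(self, kind):
        rng = np.random.default_rng(23)
        y = rng.uniform(100, 1300, size=20)
        X = np.outer(y, rng.normal(size=5)) + rng.normal(scale=10, size=(20, 5))
        cfg = PredictorConfig(model_kind=kind, seed=0)
        model = fit(X, y, cfg)
        yhat = predict(model, X)
        assert np.corrcoef(y, yhat)[0, 1] ** 2 > 0.9

    def test_random_forest_deterministic_for_seed(self):
        rng = np.random.default_rng(24)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        cfg = PredictorConfig(model_kind="random_forest", seed=7)
        a = predict(fit(X, y, cfg), X)
        b = predict(fit(X, y, cfg), X)
        np.testing.assert_array_equal(a, b)


class TestSerialization:
    def test_json_round_trip(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = fit(X, y, PredictorConfig(n_components=2), probe_ids=list("abcd"))
        again = PredictorModel.from_json(model.to_json())
        np.testing.assert_allclose(predict(again, X), predict(model, X), atol=1e-12)
        assert again.selected_probe_ids == ["a", "b", "c", "d"]

    def test_random_forest_not_json_serialisable(self):
        rng = np.random.default_rng(26)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = fit(X, y, PredictorConfig(model_kind="random_forest"))
        with pytest.raises(ValueError):
            model.to_json()
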