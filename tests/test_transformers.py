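import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foldwise.synthetic import make_edge_data
from foldwise.transformers import (
    CBPM,
    ConfoundRemover,
    correlation_screen,
    fit_cbpm,
    fit_confound_remover,
    predict_cbpm,
    remove_confounds,
)


class TestConfoundRemover:
    def test_coefficients_match_normal_equations_oracle(self):
        # oracle: explicit (A'A)^-1 A'x per feature
        rng = np.random.default_rng(3)
        n, p, q = 80, 6, 2
        C = rng.standard_normal((n, q))
        G = rng.standard_normal((q, p))
        X = C @ G + 0.3 * rng.standard_normal((n, p))
        model = fit_confound_remover(X, C)
        A = np.column_stack([np.ones(n), C])
        oracle = np.linalg.inv(A.T @ A) @ A.T @ X  # (q+1, p)
        np.testing.assert_allclose(model.coef_, oracle.T, atol=1e-10)

    def test_exactly_linear_feature_residuals_zero(self):
        age = np.linspace(20.0, 80.0, 40)
        X = (2.0 * age + 3.0)[:, None]
        model = fit_confound_remover(X, age[:, None])
        resid = remove_confounds(model, X, age[:, None])
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_zero_confound_reduces_to_mean_centering(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 3))
        C = np.zeros((30, 1))
        with pytest.warns(UserWarning, match="singular"):
            model = fit_confound_remover(X, C)
        resid = remove_confounds(model, X, C)
        np.testing.assert_allclose(resid, X - X.mean(axis=0), atol=1e-6)

    def test_residuals_orthogonal_to_confounds_on_fit_rows(self):
        rng = np.random.default_rng(17)
        n = 200
        C = rng.standard_normal((n, 3))
        X = C @ rng.standard_normal((3, 5)) + rng.standard_normal((n, 5))
        model = fit_confound_remover(X, C)
        resid = remove_confounds(model, X, C)
        for j in range(3):
            dots = np.abs(resid.T @ (C[:, j] - C[:, j].mean()))
            assert np.all(dots < 1e-8 * n)

    def test_subgroup_restricts_fitting_not_transforming(self):
        # controls follow slope 1, cases slope 3: a controls-trained model
        # residualizes controls orthogonally but not cases
        rng = np.random.default_rng(23)
        n = 300
        is_case = np.arange(n) < n // 2
        c = rng.standard_normal(n)
        slope = np.where(is_case, 3.0, 1.0)
        X = (slope * c)[:, None] + 0.1 * rng.standard_normal((n, 1))
        model = fit_confound_remover(X, c[:, None], subgroup_mask=~is_case)
        resid = remove_confounds(model, X, c[:, None])
        assert resid.shape == X.shape  # every row transformed
        ctrl_dot = abs(float(resid[~is_case, 0] @ c[~is_case]))
        case_dot = abs(float(resid[is_case, 0] @ c[is_case]))
        assert ctrl_dot < 1e-6 * n
        assert case_dot > 1.0  # mismatched slope leaves confound signal

    def test_full_vs_subgroup_fit_differ_with_group_slopes(self):
        rng = np.random.default_rng(29)
        n = 200
        is_case = np.arange(n) < n // 2
        c = rng.standard_normal(n)
        X = (np.where(is_case, 2.5, 1.0) * c)[:, None]
        full = fit_confound_remover(X, c[:, None])
        sub = fit_confound_remover(X, c[:, None], subgroup_mask=~is_case)
        assert abs(full.coef_[0, 1] - sub.coef_[0, 1]) > 0.5

    def test_empty_subgroup_errors(self):
        X = np.zeros((10, 1))
        with pytest.raises(ValueError, match="zero rows"):
            fit_confound_remover(X, np.ones((10, 1)), subgroup_mask=np.zeros(10, bool))

    def test_unseen_columns_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        C = pd.DataFrame({"c": [0.1, 0.2, 0.3, 0.4]})
        model = fit_confound_remover(X, C)
        with pytest.raises(ValueError, match="unseen"):
            remove_confounds(model, X.rename(columns={"a": "zz"}), C)


class TestCorrelationScreen:
    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        r, p = correlation_screen(X, y, "pearson")
        for j in range(8):
            rj, pj = stats.pearsonr(X[:, j], y)
            assert abs(r[j] - rj) < 1e-12
            assert abs(p[j] - pj) < 1e-9

    def test_zero_variance_feature_never_selected(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 3))
        X[:, 1] = 7.0
        y = X[:, 0]
        r, p = correlation_screen(X, y)
        assert r[1] == 0.0 and p[1] == 1.0

    def test_spearman_is_pearson_on_ranks(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        r, _ = correlation_screen(X, y, "spearman")
        for j in range(3):
            assert abs(r[j] - stats.spearmanr(X[:, j], y).statistic) < 1e-12


class TestCBPM:
    def test_perfect_feature_selected_and_predictive(self):
        rng = np.random.default_rng(7)
        n = 100
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 10))
        X[:, 4] = y  # identical to the target
        model = fit_cbpm(X, y, threshold=0.01, mode="positive")
        assert "x4" in model.pos_set
        pred = predict_cbpm(model, X)
        assert stats.pearsonr(pred, y)[0] > 0.95

    def test_worked_five_row_matrix_matches_hand_readout(self):
        # oracle: independent normal-equations evaluation of the read-out
        X = pd.DataFrame(
            {
                "a": [1.1, 2.0, 2.9, 4.2, 5.0],   # strong positive corr
                "b": [5.0, 3.9, 3.1, 2.1, 0.9],   # strong negative corr
                "c": [2.0, -1.0, 0.5, 1.5, -0.5], # junk
            }
        )
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        model = fit_cbpm(X, y, threshold=0.05, mode="both", agg="sum")
        assert model.pos_set == ["a"] and model.neg_set == ["b"]
        A = np.column_stack(
            [np.ones(5), X["a"].to_numpy(), X["b"].to_numpy()]
        )  # sum over a 1-element set is the column itself
        beta = np.linalg.inv(A.T @ A) @ A.T @ y
        expected = A @ beta
        np.testing.assert_allclose(predict_cbpm(model, X), expected, atol=1e-10)

    def test_training_transform_reproduces_aggregates(self):
        ds, _ = make_edge_data(n=80, p_edges=50, k_pos=5, k_neg=5, r=0.6, seed=3)
        X, y = ds.X, ds.y.to_numpy()
        est = CBPM(threshold=0.05, mode="both").fit(X, y)
        agg = est.transform(X)
        manual_pos = X[est.model_.pos_set].to_numpy().sum(axis=1)
        np.testing.assert_allclose(agg[:, 0], manual_pos, atol=1e-12)

    def test_row_permutation_equivariance(self):
        ds, _ = make_edge_data(n=60, p_edges=40, k_pos=4, k_neg=4, r=0.6, seed=5)
        X, y = ds.X, ds.y.to_numpy()
        model = fit_cbpm(X, y, threshold=0.05)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(
            predict_cbpm(model, X.iloc[perm]), predict_cbpm(model, X)[perm]
        )

    def test_alpha_monotonicity_of_selection(self):
        # enlarging alpha never shrinks the selected set
        for seed in range(5):
            ds, _ = make_edge_data(n=80, p_edges=60, k_pos=5, k_neg=5, r=0.3, seed=seed)
            X, y = ds.X, ds.y.to_numpy()
            prev = set()
            for alpha in (0.001, 0.01, 0.05, 0.2):
                m = fit_cbpm(X, y, threshold=alpha)
                cur = set(m.pos_set) | set(m.neg_set)
                assert prev <= cur
                prev = cur

    def test_degenerate_model_warns_and_predicts_mean(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_cbpm(X, y, threshold=1e-12)
        np.testing.assert_allclose(predict_cbpm(model, X), y.mean())

    def test_mode_both_with_one_empty_set_degrades_with_warning(self):
        rng = np.random.default_rng(13)
        n = 120
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 6))
        X[:, 0] = y + 0.1 * rng.standard_normal(n)  # only positive signal
        with pytest.warns(UserWarning, match="only the positive"):
            model = fit_cbpm(X, y, threshold=1e-6, mode="both")
        assert model.used_sets == ["positive"]
        assert len(model.readout_coef_) == 2  # intercept + one slope

    def test_mean_aggregation(self):
        ds, _ = make_edge_data(n=80, p_edges=50, k_pos=5, k_neg=5, r=0.6, seed=7)
        X, y = ds.X, ds.y.to_numpy()
        model = fit_cbpm(X, y, threshold=0.05, agg="mean")
        agg = model.aggregate(X)
        manual = X[model.pos_set].to_numpy().mean(axis=1)
        np.testing.assert_allclose(agg[:, 0], manual, atol=1e-12)
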