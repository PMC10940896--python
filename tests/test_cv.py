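import numpy as np
import pandas as pd
import pytest

from foldwise.certify import binomial_chance_band, count_correct
from foldwise.cv import (
    CVError,
    CVScheme,
    SearchSpec,
    nested_fit,
    run_cross_validation,
    scores_fingerprint,
    score,
)
from foldwise.data_model import TypedDataset, assign_types
from foldwise.pipeline import PipelineSpec, compile_pipeline
from foldwise.synthetic import make_noise_probe, make_regression_data


class TestStructure:
    def test_five_times_five_fold_gives_25_rows_per_metric(self, small_regression):
        ds, _ = small_regression
        table = run_cross_validation(
            ds,
            PipelineSpec("regression").add("linear"),
            cv=CVScheme(kind="repeated_kfold", k=5, repeats=5, seed=0),
            metrics=["neg_mae", "r2"],
            seed=0,
        )
        assert len(table) == 25 * 2
        per_metric = table.groupby("metric_name").size()
        assert (per_metric == 25).all()
        assert (table["n_train"] + table["n_test"] == ds.n_samples).all()

    def test_leave_one_out_gives_n_rows(self):
        ds, _ = make_regression_data(n=23, p=3, k_informative=3, seed=1)
        table = run_cross_validation(
            ds,
            PipelineSpec("regression").add("linear"),
            cv=CVScheme(kind="leave_one_out"),
            metrics=["neg_mae"],
            seed=0,
        )
        assert len(table) == 23
        assert (table["n_test"] == 1).all()

    def test_fold_partitions_disjoint_and_cover(self, small_regression):
        ds, _ = small_regression
        _, insp = run_cross_validation(
            ds,
            PipelineSpec("regression").add("linear"),
            cv=CVScheme(kind="repeated_kfold", k=4, repeats=2, seed=3),
            metrics=["r2"],
            return_inspector=True,
            seed=3,
        )
        for repeat in (0, 1):
            test_ids = [
                rec.test_ids for rec in insp.records if rec.repeat == repeat
            ]
            flat = [i for ids in test_ids for i in ids]
            assert len(flat) == len(set(flat)) == ds.n_samples

    def test_group_cv_never_splits_a_group(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "x": rng.standard_normal(60),
                "g": np.repeat(np.arange(12), 5),
                "y": rng.standard_normal(60),
            }
        )
        ds = assign_types(TypedDataset(table=table), target="y", groups="g")
        _, insp = run_cross_validation(
            ds,
            PipelineSpec("regression").add("linear"),
            cv=CVScheme(kind="group_kfold", k=4),
            metrics=["r2"],
            return_inspector=True,
            seed=0,
        )
        groups = ds.table["g"]
        for rec in insp.records:
            assert not set(groups.loc[rec.train_ids]) & set(groups.loc[rec.test_ids])


class TestContracts:
    def test_determinism_across_runs(self, small_regression):
        ds, _ = small_regression
        ps = PipelineSpec("regression").add("zscore").add("rf", n_estimators=10)
        runs = [
            run_cross_validation(ds, ps, metrics=["r2"], seed=42) for _ in range(2)
        ]
        assert scores_fingerprint(runs[0]) == scores_fingerprint(runs[1])

    def test_dummy_regressor_fold_r2_nonpositive(self, small_regression):
        ds, _ = small_regression
        table = run_cross_validation(
            ds, PipelineSpec("regression").add("dummy"), metrics=["r2"], seed=0
        )
        assert (table["score"] <= 1e-12).all()

    def test_noise_classification_at_chance(self):
        ds, _ = make_noise_probe(n=200, p=10, task="classification", seed=5)
        _, insp = run_cross_validation(
            ds,
            PipelineSpec("classification").add("zscore").add("svm"),
            cv=CVScheme(kind="repeated_kfold", k=5, repeats=3, seed=5),
            metrics=["accuracy"],
            return_inspector=True,
            seed=5,
        )
        correct, total = count_correct(insp)
        lo, hi = binomial_chance_band(total, level=0.999)
        assert lo <= correct / total <= hi

    def test_stratified_with_continuous_target_rejected(self, small_regression):
        ds, _ = small_regression
        with pytest.raises(CVError, match="classification"):
            run_cross_validation(
                ds,
                PipelineSpec("regression").add("linear"),
                cv=CVScheme(kind="stratified_kfold", k=5, seed=0),
                metrics=["r2"],
                seed=0,
            )

    def test_missing_values_rejected_without_imputer(self):
        table = pd.DataFrame(
            {"a": [1.0, np.nan, 3.0, 4.0, 5.0, 6.0], "y": [0.0, 1, 2, 3, 4, 5]}
        )
        ds = assign_types(TypedDataset(table=table), target="y")
        with pytest.raises(CVError, match="'a'"):
            run_cross_validation(
                ds,
                PipelineSpec("regression").add("linear"),
                cv=CVScheme(k=2, seed=0),
                metrics=["r2"],
                seed=0,
            )

    def test_missing_values_allowed_with_imputer(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {"a": rng.standard_normal(30), "y": rng.standard_normal(30)}
        )
        table.loc[3, "a"] = np.nan
        ds = assign_types(TypedDataset(table=table), target="y")
        table_out = run_cross_validation(
            ds,
            PipelineSpec("regression").add("impute").add("linear"),
            cv=CVScheme(k=3, seed=0),
            metrics=["r2"],
            seed=0,
        )
        assert table_out["score"].notna().all()

    def test_absent_class_warns_and_scores_nan(self):
        rng = np.random.default_rng(1)
        n = 30
        table = pd.DataFrame({"x": rng.standard_normal(n)})
        y = np.array(["a"] * 15 + ["b"] * 14 + ["c"])  # one singleton class
        table["y"] = y
        ds = assign_types(TypedDataset(table=table), target="y")
        with pytest.warns(UserWarning, match="absent"):
            out = run_cross_validation(
                ds,
                PipelineSpec("classification").add("logit"),
                cv=CVScheme(k=3, seed=2),
                metrics=["accuracy"],
                seed=2,
            )
        assert out["score"].isna().sum() == 1
        assert len(out) == 3  # NaN fold kept, not dropped


class TestNestedSearch:
    def test_grid_enumerates_full_product(self, small_regression):
        ds, _ = small_regression
        ps = (
            PipelineSpec("regression")
            .add("zscore")
            .add("svm", C=[1.0, 10.0], kernel=["linear", "rbf"])
        )
        comp = compile_pipeline(ps, ds)
        X = comp.encode(ds)
        _, _, records = nested_fit(
            X, ds.y.to_numpy(), comp, SearchSpec(), seed=0,
            outer_scheme=CVScheme(seed=0),
        )
        assert len(records["params"]) == 4

    def test_single_candidate_equals_no_search(self, small_regression):
        # a singleton grid compiles to the identical fixed pipeline
        ds, _ = small_regression
        fixed = PipelineSpec("regression").add("zscore").add("svm", C=1.0)
        single = PipelineSpec("regression").add("zscore").add("svm", C=[1.0])
        t_fixed = run_cross_validation(ds, fixed, metrics=["r2"], seed=7)
        t_single = run_cross_validation(ds, single, metrics=["r2"], seed=7)
        np.testing.assert_allclose(
            t_fixed["score"].to_numpy(), t_single["score"].to_numpy(), atol=1e-15
        )

    def test_dominant_candidate_wins_across_seeds(self):
        # planted separation: an almost-unregularized SVM cannot fit, C=10 can
        wins = 0
        n_seeds = 10
        for s in range(n_seeds):
            rng = np.random.default_rng(100 + s)
            n = 120
            y = np.repeat([0, 1], n // 2)
            X = rng.standard_normal((n, 4)) + 1.2 * y[:, None]
            table = pd.DataFrame(X, columns=list("abcd"))
            table["y"] = y
            ds = assign_types(TypedDataset(table=table), target="y")
            ps = (
                PipelineSpec("classification")
                .add("zscore")
                .add("svm", C=[1e-6, 10.0])
            )
            _, insp = run_cross_validation(
                ds, ps, cv=CVScheme(k=5, seed=s), metrics=["accuracy"],
                return_inspector=True, seed=s,
            )
            params = insp.fold_params()
            chosen = params[(params["step"] == "svm") & (params["param"] == "C")]
            if (chosen["value"] == 10.0).all():
                wins += 1
        assert wins >= 9  # >= 90% of seeds at this scale

    def test_tie_break_is_first_in_enumeration(self, small_regression):
        ds, _ = small_regression
        # duplicate candidate values tie exactly; the first must win
        ps = PipelineSpec("regression").add("ridge", alpha=[2.0, 2.0 + 0.0, 5.0])
        comp = compile_pipeline(ps, ds)
        X = comp.encode(ds)
        best, _, records = nested_fit(
            X, ds.y.to_numpy(), comp, SearchSpec(), seed=1,
            outer_scheme=CVScheme(seed=1),
        )
        assert best["ridge__estimator__alpha"] == 2.0


class TestMetrics:
    def test_perfect_predictions_neg_mae_zero(self):
        ds, _ = make_regression_data(n=40, p=2, k_informative=2, noise_sd=0.0, seed=2)
        comp = compile_pipeline(PipelineSpec("regression").add("linear"), ds).fit(ds)
        X = comp.encode(ds)
        assert abs(score(comp.pipeline, X, ds.y.to_numpy(), "neg_mae")) < 1e-10

    def test_constant_predictor_train_r2_zero(self):
        ds, _ = make_regression_data(n=40, p=2, k_informative=2, seed=3)
        comp = compile_pipeline(PipelineSpec("regression").add("dummy"), ds).fit(ds)
        X = comp.encode(ds)
        assert abs(score(comp.pipeline, X, ds.y.to_numpy(), "r2")) < 1e-12

    def test_neg_mae_matches_direct_formula(self):
        # oracle: -mean(|err|) computed directly from fold predictions
        ds, _ = make_regression_data(n=60, p=4, k_informative=4, seed=4)
        table, insp = run_cross_validation(
            ds,
            PipelineSpec("regression").add("linear"),
            metrics=["neg_mae"],
            return_inspector=True,
            seed=4,
        )
        preds = insp.fold_predictions()
        for (_, fold), grp in preds.groupby(["repeat_idx", "fold_idx"]):
            manual = -np.mean(np.abs(grp["y_true"] - grp["y_pred"]))
            got = table[
                (table["fold_idx"] == fold) & (table["metric_name"] == "neg_mae")
            ]["score"].iloc[0]
            assert abs(manual - got) < 1e-12

    def test_unknown_metric_rejected(self, small_regression):
        ds, _ = small_regression
        with pytest.raises(CVError, match="unknown metric"):
            run_cross_validation(
                ds, PipelineSpec("regression").add("linear"), metrics=["mae"], seed=0
            )
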