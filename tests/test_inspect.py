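import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import RepeatedKFold

from foldwise.cv import CVScheme, SearchSpec, run_cross_validation
from foldwise.data_model import TypedDataset
from foldwise.inspect import InspectError, preprocess_until
from foldwise.pipeline import PipelineSpec, compile_pipeline
from foldwise.synthetic import make_edge_data, make_regression_data
from foldwise.transformers import fit_cbpm


@pytest.fixture(scope="module")
def run_5x5():
    ds, _ = make_regression_data(n=100, p=6, k_informative=3, seed=31)
    table, insp = run_cross_validation(
        ds,
        PipelineSpec("regression").add("zscore").add("linear"),
        cv=CVScheme(kind="repeated_kfold", k=5, repeats=5, seed=31),
        metrics=["neg_mae"],
        return_inspector=True,
        seed=31,
    )
    return ds, table, insp


class TestFoldPredictions:
    def test_5x5_on_100_samples_gives_500_rows(self, run_5x5):
        _, _, insp = run_5x5
        assert len(insp.fold_predictions()) == 500

    def test_every_sample_tested_once_per_repeat(self, run_5x5):
        _, _, insp = run_5x5
        counts = insp.fold_predictions().groupby("sample_id").size()
        assert (counts == 5).all()

    def test_scores_recomputable_from_predictions(self, run_5x5):
        # internal consistency: ScoresTable and predictions agree to 1e-12
        _, table, insp = run_5x5
        preds = insp.fold_predictions()
        for (rep, fold), grp in preds.groupby(["repeat_idx", "fold_idx"]):
            manual = -np.mean(np.abs(grp["y_true"] - grp["y_pred"]))
            row = table[(table["repeat_idx"] == rep) & (table["fold_idx"] == fold)]
            assert abs(manual - row["score"].iloc[0]) < 1e-12

    def test_prediction_summary_counts(self, run_5x5):
        _, _, insp = run_5x5
        summary = insp.prediction_summary()
        assert (summary["n_appearances"] == 5).all()
        assert len(summary) == 100

    def test_fold_index_map_matches_standalone_splitter(self, run_5x5):
        ds, _, insp = run_5x5
        splitter = RepeatedKFold(n_splits=5, n_repeats=5, random_state=31)
        for i, (train, test) in enumerate(splitter.split(ds.X)):
            rep, fold = divmod(i, 5)
            rec = insp.fold_index_map[(rep, fold)]
            assert list(ds.sample_ids[test]) == rec["test"]
            assert list(ds.sample_ids[train]) == rec["train"]


class TestFoldParams:
    def test_fixed_params_shown_without_search(self):
        ds, _ = make_regression_data(n=60, p=4, k_informative=4, seed=1)
        _, insp = run_cross_validation(
            ds,
            PipelineSpec("regression").add("ridge", alpha=2.5),
            metrics=["r2"],
            return_inspector=True,
            seed=1,
        )
        params = insp.fold_params()
        alphas = params[(params["step"] == "ridge") & (params["param"] == "alpha")]
        assert len(alphas) == 5 and (alphas["value"] == 2.5).all()

    def test_search_records_one_choice_per_fold(self):
        ds, _ = make_regression_data(n=80, p=5, k_informative=5, seed=2)
        _, insp = run_cross_validation(
            ds,
            PipelineSpec("regression").add("ridge", alpha=[0.1, 10.0]),
            search=SearchSpec(),
            metrics=["r2"],
            return_inspector=True,
            seed=2,
        )
        params = insp.fold_params()
        chosen = params[(params["step"] == "ridge") & (params["param"] == "alpha")]
        assert len(chosen) == 5
        assert set(chosen["value"]).issubset({0.1, 10.0})

    def test_cbpm_summary_matches_direct_refit_on_training_rows(self):
        ds, _ = make_edge_data(n=120, p_edges=80, k_pos=8, k_neg=8, r=0.5, seed=3)
        ps = PipelineSpec("regression").add("cbpm", threshold=0.05).add("linear")
        _, insp = run_cross_validation(
            ds, ps, cv=CVScheme(k=4, seed=3), metrics=["r2"],
            return_inspector=True, seed=3,
        )
        params = insp.fold_params()
        for rec in insp.records:
            train = ds.table.loc[rec.train_ids]
            oracle = fit_cbpm(
                train[ds.feature_names], train[ds.target].to_numpy(), threshold=0.05
            )
            sub = params[
                (params["repeat_idx"] == rec.repeat)
                & (params["fold_idx"] == rec.fold)
                & (params["step"] == "cbpm")
            ].set_index("param")["value"]
            assert sub["n_pos_selected"] == len(oracle.pos_set)
            assert sub["n_neg_selected"] == len(oracle.neg_set)

    def test_summaries_only_mode_drops_models_keeps_predictions(self):
        ds, _ = make_regression_data(n=50, p=3, k_informative=3, seed=4)
        _, insp = run_cross_validation(
            ds,
            PipelineSpec("regression").add("linear"),
            metrics=["r2"],
            return_inspector=True,
            store_fold_models=False,
            seed=4,
        )
        assert len(insp.fold_predictions()) == 50
        with pytest.raises(InspectError, match="not stored"):
            insp.fold_model(0, 0)


@pytest.fixture(scope="module")
def fitted_chain():
    ds, _ = make_regression_data(n=80, p=10, k_informative=5, seed=7)
    ps = (
        PipelineSpec("regression")
        .add("variance_threshold", threshold=1e-5)
        .add("zscore")
        .add("pca", n_components=4)
        .add("linear")
    )
    comp = compile_pipeline(ps, ds).fit(ds)
    return ds, comp


class TestPreprocessUntil:
    def test_until_first_step_returns_thresholded_features(self, fitted_chain):
        ds, comp = fitted_chain
        out = preprocess_until(comp, ds, "variance_threshold")
        assert out.shape == (80, 10)  # nothing below threshold on this data

    def test_until_zscore_standardizes(self, fitted_chain):
        ds, comp = fitted_chain
        out = preprocess_until(comp, ds, "zscore")
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)

    def test_until_pca_matches_projection_oracle(self, fitted_chain):
        # oracle: project the z-scored data onto the fitted components
        ds, comp = fitted_chain
        z = preprocess_until(comp, ds, "zscore").to_numpy()
        got = preprocess_until(comp, ds, "pca").to_numpy()
        pca = comp.pipeline.named_steps["pca"].transformer_
        expected = (z - pca.mean_) @ pca.components_.T
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_model_step_suggests_predict(self, fitted_chain):
        ds, comp = fitted_chain
        with pytest.raises(InspectError, match="predict"):
            preprocess_until(comp, ds, "linear")

    def test_unknown_step_lists_names(self, fitted_chain):
        ds, comp = fitted_chain
        with pytest.raises(InspectError, match="available steps"):
            preprocess_until(comp, ds, "nope")

    def test_works_on_engine_fold_model(self):
        ds, _ = make_regression_data(n=60, p=4, k_informative=4, seed=8)
        _, insp = run_cross_validation(
            ds,
            PipelineSpec("regression").add("zscore").add("linear"),
            metrics=["r2"],
            return_inspector=True,
            seed=8,
        )
        fold_pipe = insp.fold_model(0, 0)
        out = preprocess_until(fold_pipe, ds, "zscore")
        assert out.shape == (60, 4)
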