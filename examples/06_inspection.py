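"""Look inside a finished CV run: intermediate data and fold-wise detail.

``preprocess_until`` replays a fitted pipeline's transformers up to any
step (e.g. to inspect PCA scores); the inspector exposes per-fold test
predictions and fitted-parameter summaries.
"""

from foldwise import PipelineSpec, compile_pipeline, preprocess_until, run_cross_validation
from foldwise.synthetic import make_regression_data

ds, _ = make_regression_data(n=120, p=10, k_informative=5, seed=9)

ps = (
    PipelineSpec("regression")
    .add("variance_threshold", threshold=1e-5)
    .add("zscore")
    .add("pca", n_components=4)
    .add("linear")
)

compiled = compile_pipeline(ps, ds).fit(ds)
pcs = preprocess_until(compiled, ds, "pca")
print("data transformed up to the pca step (first rows):")
print(pcs.head(3).round(3).to_string())

table, inspector = run_cross_validation(
    ds, ps, metrics=["r2"], return_inspector=True, seed=9
)
preds = inspector.fold_predictions()
print(f"\nfold predictions table: {len(preds)} rows (one per test sample)")
print(preds.head(3).to_string(index=False))

params = inspector.fold_params()
evr = params[params["param"].str.startswith("explained_variance_ratio")]
print("\nper-fold PCA explained-variance summary rows:")
print(evr.head(5).to_string(index=False))
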