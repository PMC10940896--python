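"""Evaluate a standardize+SVM pipeline with 5-fold cross-validation.

Generates a small linear-regression dataset, runs the pipeline through
the engine and prints the tidy per-fold scores plus their summary.
"""

from foldwise import PipelineSpec, run_cross_validation, summarize_scores
from foldwise.synthetic import make_regression_data

ds, truth = make_regression_data(n=200, p=10, k_informative=5, noise_sd=1.0, seed=7)
print(ds)

ps = PipelineSpec("regression").add("zscore").add("svm")
table = run_cross_validation(ds, ps, metrics=["neg_mae", "r2"], seed=7)

print("\nper-fold scores (one row per repeat x fold x metric):")
print(table[["repeat_idx", "fold_idx", "metric_name", "score"]].to_string(index=False))

print("\nsummary (higher is better; neg_mae = 0 would be a perfect fit):")
print(summarize_scores(table).to_string(index=False))
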