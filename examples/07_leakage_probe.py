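"""Catch data leakage in the act.

On pure-noise data every honest evaluation must score at chance.  The
engine does; a reference that selects the 10 most target-correlated of
1000 noise features on ALL samples *before* splitting does not — the
classic pre-split selection leak.
"""

from foldwise.certify import (
    binomial_chance_band,
    count_correct,
    leaky_topk_selection_cv,
)
from foldwise import CVScheme, PipelineSpec, run_cross_validation
from foldwise.synthetic import make_noise_probe

ds, _ = make_noise_probe(n=400, p=1000, task="classification", seed=4)

_, inspector = run_cross_validation(
    ds,
    PipelineSpec("classification").add("zscore").add("svm"),
    cv=CVScheme(kind="stratified_kfold", k=5, seed=4),
    metrics=["accuracy"],
    return_inspector=True,
    seed=4,
)
correct, total = count_correct(inspector)
lo, hi = binomial_chance_band(total, level=0.99)
print(f"engine (selection inside folds): accuracy {correct / total:.3f}")
print(f"99% chance band for {total} predictions: [{lo:.3f}, {hi:.3f}]")

leaky_correct, leaky_total = leaky_topk_selection_cv(ds, n_select=10, seed=4)
print(f"leaky reference (pre-split selection): accuracy {leaky_correct / leaky_total:.3f}")
print(
    "\nSame data, same model — the only difference is WHERE the feature "
    "selection was computed. The inflated number is pure leakage."
)
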