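# foldwise

Leakage-free cross-validation for tabular supervised learning, built for
researchers — particularly in neuroscience, biostatistics and
epidemiology — who need trustworthy generalization estimates without
hand-assembling scikit-learn plumbing for every study.

Two pitfalls inflate most over-optimistic CV results: **data leakage**
(preprocessing or feature selection computed on the complete dataset
before splitting) and **hyperparameter overfitting** (tuning by reading
outer-fold test scores).  foldwise makes both structurally impossible:
pipelines are compiled into one trainable object refitted from scratch
inside every training partition, and any hyperparameter grid is searched
automatically in an *inner* CV nested within each outer training fold.

What's in the box:

* **Typed pipelines** — columns carry type labels (`continuous`,
  `categorical`, `confound`, …); each step declares which types it
  touches, everything else passes through bit-identical.
* **One evaluation entry point** — `run_cross_validation(ds, pipeline,
  cv, metrics, …)` returns a tidy per-(repeat, fold, metric) scores
  table, with nested grid search engaged automatically whenever a step
  carries candidate values.
* **Corrected model comparison** — the fold-dependency-corrected paired
  t-test:

  `t = mean(d) / sqrt((1/J + n_test/n_train) · var(d))`, dof `J−1`,

  where `d` are per-fold score differences of two models evaluated on
  identical folds.  The naive paired t-test rejects ~45% of true nulls
  at α = 0.05 in the repeated-CV setting; the corrected one is near
  nominal.
* **Confound regression** (per-feature OLS residualization), optionally
  trained on a subgroup (e.g. healthy controls only) and applied to all
  rows — inside the CV, so coefficients never see test data.
* **CBPM** (Connectome-Based Predictive Modelling): correlation
  screening at a significance threshold α, sign-split aggregation into
  one or two summary features, linear read-out.
* **Fold-wise inspection** — per-fold test predictions, chosen
  hyperparameters, fitted-parameter summaries, and `preprocess_until`
  to replay a fitted pipeline up to any step.
* **Certification probes** — pure-noise datasets plus deliberately
  leaky reference implementations that demonstrate, in the test suite,
  that the engine's split discipline is load-bearing.

## Worked example

```python
from foldwise import CVScheme, PipelineSpec, pairwise_compare, run_cross_validation
from foldwise.synthetic import make_regression_data

ds, _ = make_regression_data(n=200, p=10, k_informative=5, noise_sd=1.0, seed=5)
scheme = CVScheme(kind="repeated_kfold", k=5, repeats=5, seed=5)

tables = []
for name in ["linear", "svm", "dummy"]:
    ps = PipelineSpec("regression").add("zscore").add(name, name=name)
    tables.append(run_cross_validation(ds, ps, cv=scheme, metrics=["neg_mae"], seed=5))

print(pairwise_compare(tables).to_string(index=False))
```

prints

```
model_a model_b  mean_diff    t_stat      p_value  dof
 linear     svm   0.309755  4.596321 1.159170e-04   24
 linear   dummy   1.360572 10.235859 3.111664e-10   24
    svm   dummy   1.050817 10.600798 1.554124e-10   24
```

Each model was scored on the same 25 folds (5×5 CV) with negated mean
absolute error, so higher is better.  `mean_diff > 0` means the first
model scored higher; the linear model beats the SVM by 0.31 MAE units
(corrected p ≈ 1.2×10⁻⁴ on 24 dof) and both crush the mean-predicting
dummy baseline.

Catching leakage on data with no signal at all
(`examples/07_leakage_probe.py`):

```
engine (selection inside folds): accuracy 0.492
99% chance band for 400 predictions: [0.435, 0.565]
leaky reference (pre-split selection): accuracy 0.620
```

Same noise data, same SVM — the only difference is where the top-10
feature selection was computed.  The 0.620 is pure leakage.

Subgroup-trained confound removal (`examples/04_confound_removal.py`),
on a synthetic age-confounded case/control cohort:

```
without removal  : accuracy 0.588, misclassified age-gap p = 1.98e-23
with removal     : accuracy 0.488, misclassified age-gap p = 6.01e-02
```

Without removal the classifier rides the age signal and its errors are
age-biased; with controls-trained confound regression (refit inside
every training fold) both effects collapse to chance.

More: `examples/01_basic_cv.py` (first run), `02_hyperparameter_search`
(nested grids), `05_cbpm`, `06_inspection`.

## Command line

A thin config-driven front end wraps the library:

```bash
foldwise generate confounded --n 498 --p 68 --seed 1 --out data.csv
foldwise run experiment.yaml          # scores/predictions/params CSVs + snapshot
foldwise compare run_a/scores.csv run_b/scores.csv --out cmp/
foldwise inspect run/
```

The resolved-config snapshot written by `run` makes any bundle
re-executable with identical scores.

## Documentation

`docs/methods.md` describes the models and procedures, the correction's
derivation, the synthetic generators and what passing tests do (and do
not) certify, and the package's numerical conventions.
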