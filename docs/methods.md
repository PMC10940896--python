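# Methods

## The problem

Cross-validation (CV) estimates how well a supervised pipeline
generalizes by repeatedly fitting on one part of the data and scoring on
the held-out rest.  The estimate is only valid if *every* fitted
quantity — standardization means, PCA bases, selected features, confound
coefficients, chosen hyperparameters — is computed from the training
partition of each split.  Two failure modes dominate applied work:

1. **Leakage** — preprocessing or feature selection computed on the
   complete dataset before splitting, so the training data reflects the
   test data.
2. **Hyperparameter overfitting** — tuning by repeatedly reading
   outer-fold test scores, which turns the test folds into training
   signal for the tuning step.

foldwise's engine makes both mistakes structurally impossible: pipelines
are compiled into a single trainable object fitted from scratch inside
every outer training partition, and any hyperparameter grid is searched
in an *inner* CV that partitions only that outer-training data, with the
refit winner scored exactly once on the outer test fold.

## Typed pipelines

Columns carry roles (target, features, optional grouping) and each
feature carries one type label (`continuous` by default, or
`categorical`, `confound`, any user label).  Every pipeline step takes a
type selector; the compiled step transforms the selected columns and
passes the rest through bit-identically.  Produced columns are named
deterministically (`step__original` for one-to-one steps, `step__k` for
dimension-changing ones) and re-labelled so later steps can address
them.  Internally the type label is encoded into the column name while
the frame travels through the scikit-learn pipeline; the public surface
always shows clean names.

Two conventions worth knowing:

* Confound columns are consumed by a `confound_removal` step and dropped
  afterwards (they were regressors, not features); `keep_confounds=True`
  reverses this.  Dropping prevents accidental double use of the
  confound as a predictor.
* The model step also accepts a selector (wildcard by default), so a
  column can travel with the data for a transformer's benefit (e.g. a
  subgroup indicator) without ever becoming a model feature.  Columns a
  transformer needs but that are not features are carried under a
  reserved `aux` label that wildcards never match.

## Nested search

A list of two or more candidate values attached to any step parameter
marks the pipeline as needing search (singletons and tuples are fixed
values).  The default searcher enumerates the full cartesian product of
all step grids (grid search; a random sampler is available), scores each
candidate by the tuning metric in an inner 5-fold CV of the
outer-training partition, breaks ties by first-in-enumeration order, and
refits the winner on the full outer-training partition.  The inner
scheme inherits stratification or grouping from the outer scheme.  All
error metrics are negated so that higher is better everywhere.

## Corrected model comparison

Fold scores from a shared CV are dependent: any two training sets
overlap in roughly (k-2)/(k-1) of their samples, and for repeated k-fold
every pair of repeats re-uses the same data.  The naive paired t-test on
per-fold score differences treats the J fold differences as independent
and is badly anticonservative.  The corrected resampled t-test used here
is

    t = mean(d) / sqrt( (1/J + n_test/n_train) * var(d) ),   dof = J - 1

with `var` the unbiased sample variance.  Derivation sketch: model the
fold differences as exchangeable with common variance s² and common
between-fold correlation rho.  The variance of their mean is
s²(1/J + rho(J-1)/J); the correction substitutes the train/test overlap
ratio rho = n_test/(n_test+n_train) motivated by how much of each
training set is "new" relative to another fold, and estimates the
residual variance by var(d), giving exactly the (1/J + n_test/n_train)
inflation.  For repeated k-fold the ratio is computed from the scheme as
1/(k-1) (fold-size jitter is ignored; the correction is itself an
approximation, and per-fold counts would add noise without adding
validity).  Confidence bars in the scores plot use the same corrected
variance and are labelled as such.

**Calibration check.**  The type-I-error simulation draws fold-score
differences directly from the exchangeable null the correction is built
for: compound-symmetric Gaussians with between-fold correlation
rho = 1/k, realized as a shared dataset-level component plus independent
fold noise.  In that regime the corrected statistic is exactly
t-distributed and lands near the nominal 5% (≈ 0.046 at 2000
simulations) while the naive test rejects ≈ 45% of nulls.  Simulating
the null with *real* repeated CVs of two equivalent models on shared
data instead produces far stronger dependence than the correction
assumes, and the corrected test becomes very conservative (type-I error
→ 0.001 in our pilots); that direction of error is the safe one, and it
is the documented, well-known behaviour of this correction.  The
compound-symmetric simulation is kept because it isolates the property
the correction claims: near-nominal error under its own dependency
model, against gross naive inflation on identical draws.

## Confound regression

Each feature is regressed by ordinary least squares on the confounds
plus an intercept; the residual replaces the feature.  OLS per feature
is the literature-standard choice for "confound regression"; no
nonlinear variants are offered.  A singular design (constant confound,
exact collinearity) falls back to ridge with penalty 1e-8 and a warning.
The regression may be trained on a subgroup — typically the healthy
controls, specified as `(column, values)` where the column may be the
target itself — while the learned coefficients are applied to **all**
rows: the subgroup restricts fitting, never transforming.  On the
fitting rows, residuals are exactly orthogonal to the confounds; on
other rows they generally are not, which is precisely the point when
case and control confound slopes differ.

## CBPM

Connectome-Based Predictive Modelling: every (edge) feature is screened
by correlation with the target (Pearson by default, with the exact
t-transform p-value; Spearman optional), survivors of the two-sided
p < alpha screen are split by correlation sign, each sign set is
aggregated per sample (sum by default, mean optional), and a linear
read-out is fitted on the one or two aggregates.  Defaults: alpha =
0.01, Pearson, both sets, sum — matching the method's common usage.
Prediction aggregates test rows with the *training-selected* sets; there
is no re-selection at test time.  Zero-variance features get r = 0,
p = 1 and can never be selected.  If a required set is empty the model
degrades (both→single with a warning; nothing selected → degenerate,
predicting the training mean) rather than erroring mid-CV.  Screening
p-values are deliberately **not** multiplicity-corrected: the method is
defined by raw per-feature thresholding, and the surrounding CV — not
the screen — carries the inferential burden.  Consequently the expected
false-selection rate among null features is alpha itself.

## Synthetic generators

All test inputs are generated with known ground truth; nothing is
downloaded.  The generators emulate the statistical skeleton of three
recurring neuroimaging designs, not their content:

* `make_regression_data` — linear signal in k of p Gaussian features
  (region-level morphometry → continuous outcome).
* `make_confounded_data` — case/control cohort (defaults n = 498,
  p = 68, about the size of a typical clinical tabular dataset) whose
  features carry an age signal (`x = target_effect*t +
  gamma*z(age) + noise`) and whose groups differ in age by ~6 years, so
  age alone supports above-chance classification.  `target_effect` is 0
  by default: the pure-confound scenario where removal should send
  accuracy to chance.  `group_specific_slopes` makes case and control
  confound slopes differ, which is what makes subgroup-trained and
  full-sample removal distinguishable.
* `make_edge_data` — planted-correlation edges via the exact
  construction `x = r*z_y + sqrt(1-r²)*z` (population correlation
  exactly ±r; defaults n = 300, 500 edges, 20 + 20 planted at |r| = 0.4,
  a mid-sized connectome-prediction regime).  `vectorize_symmetric`
  implements the standard unique-edge vectorization (m parcels →
  m(m-1)/2 features).
* `make_noise_probe` — guaranteed-null data (features independent of the
  target; classification labels exactly balanced), the substrate of the
  leakage certification.

What the generators do **not** emulate: spatial structure and smoothness
of imaging-derived features, feature-feature correlation beyond the
planted target correlation, heavy tails, site effects, missingness
patterns.  Passing tests therefore certify the *procedural* properties
(split discipline, recovery of planted structure, calibration) — they do
not certify performance on any real cohort.

## Certification probes

The certification module pairs the engine with deliberately flawed
references that exist only to be caught:

* **Leakage probe**: on noise data (n = 400, p = 1000, 100 datasets) the
  engine's pooled test accuracy must lie inside the central 99% binomial
  band around 0.5, while pre-split selection of the 10 most
  target-correlated features rejects the chance null at p < 0.001.
  Stratified 5-fold is used in both arms: with *un*stratified folds on
  exactly balanced null data, accuracy sits systematically below chance
  (a training-fold majority class is necessarily a test-fold minority —
  a fold-composition artifact, not leakage), whereas under
  stratification the chance level is exact by label-exchange symmetry.
* **Nesting probe**: the tuned hyperparameter is the size of a
  univariate selection feeding an SVM — candidates exchangeable under
  the null, so tune-on-test's max-over-candidates is optimistic (mean
  gap ≈ +0.03 accuracy) while the nested estimate is not.  A
  hyperparameter with a deterministic ordering on noise (e.g. a ridge
  penalty, where more shrinkage always wins) would make the two
  procedures agree trivially and demonstrate nothing.
* **Calibration probe**: described under the corrected test above.

## Numerical and bookkeeping choices

* Determinism: one master seed; per-fold and per-component substreams
  derived by counter-based `SeedSequence` spawning, so results are
  identical across runs and process restarts.  `fit_time` is wall-clock
  and therefore excluded from the determinism fingerprint
  (`scores_fingerprint`).
* NaN fold scores (e.g. a class missing from a training fold) are kept
  in the table and excluded from means with a warning; comparisons drop
  NaN folds pairwise.
* Missing values are accepted at load time and rejected at CV time
  unless the pipeline contains an imputation step — silent imputation is
  itself a leakage vector.
* Problem sizes in the test-suite probes (100 noise datasets at
  n = 400 × p = 1000; 2000 calibration draws; 50 CBPM datasets; 20
  confound cohorts) were chosen as the smallest runs whose Monte-Carlo
  error is clearly inside the asserted bands.

## Known limitations

* Strictly linear pipelines; no DAGs, no caching of intermediate
  transforms, no target transformation.
* Searchers: grid and random only.
* The corrected t-test is an approximation; with few folds and strong
  real-data dependence it errs conservative.
* CBPM supports sum/mean aggregation and Pearson/Spearman screening
  only; confound regression is linear-Gaussian only.
* The registry ships the common estimator families; relevance vector
  regression resolves only if a compatible implementation is registered
  by the user.
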