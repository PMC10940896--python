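"""Certification probes: demonstrate that the engine's split discipline
is load-bearing.

Three demonstrations, each pairing the engine's leakage-free path with a
deliberately flawed reference:

* **Leakage**: on pure-noise data, the engine scores at chance while a
  reference that selects the most target-correlated features on ALL
  samples *before* splitting scores far above chance.
* **Nesting**: on noise data, picking a hyperparameter by its outer-fold
  test score ("tune on test") yields a systematically higher best score
  than the honestly nested estimate.
* **Correction calibration**: under an exchangeable null with the
  between-fold correlation the corrected t-test is built for
  (rho = n_test/(n_test+n_train)), the corrected test's type-I error is
  close to nominal while the naive paired t-test's is grossly inflated.

The flawed references exist only to be caught; they are never part of an
evaluation path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cv import CVScheme, SearchSpec, run_cross_validation
from .data_model import TypedDataset, all_except
from .pipeline import PipelineSpec
from .synthetic import make_confounded_data, make_edge_data, make_noise_probe
from .transformers import correlation_screen, fit_cbpm

__all__ = [
    "binomial_chance_band",
    "count_correct",
    "leaky_topk_selection_cv",
    "leakage_certification",
    "nesting_certification",
    "corrected_ttest_calibration",
    "misclassified_age_gap",
    "confound_pattern_certification",
    "cbpm_recovery",
]


def binomial_chance_band(n_total: int, level: float = 0.99) -> tuple:
    """Central ``level`` band for the accuracy of n_total fair coin flips."""
    lo = sps.binom.ppf((1 - level) / 2, n_total, 0.5) / n_total
    hi = sps.binom.ppf(1 - (1 - level) / 2, n_total, 0.5) / n_total
    return float(lo), float(hi)


def count_correct(inspector) -> tuple:
    """(n_correct, n_total) over all test predictions of a CV run."""
    preds = inspector.fold_predictions()
    n_correct = int((preds["y_true"] == preds["y_pred"]).sum())
    return n_correct, len(preds)


def _noise_pipeline(problem_type: str = "classification") -> PipelineSpec:
    return PipelineSpec(problem_type).add("zscore").add("svm")


def leaky_topk_selection_cv(
    ds: TypedDataset,
    n_select: int = 10,
    cv: Optional[CVScheme] = None,
    seed: int = 0,
) -> tuple:
    """DELIBERATELY LEAKY reference: univariate feature selection computed
    on the complete dataset before splitting, then an otherwise ordinary
    CV on the pre-selected features.

    Returns ``(n_correct, n_total)``.  This reproduces the textbook
    leakage pitfall and must beat chance on pure noise — which is exactly
    what certifies that the engine's in-fold selection does not.
    """
    y = ds.y.to_numpy()
    y_num = pd.factorize(ds.y)[0] if ds.y.dtype == object else y
    X = ds.X.to_numpy(dtype=float)
    r, _ = correlation_screen(X, y_num.astype(float), "pearson")
    top = np.argsort(-np.abs(r), kind="stable")[:n_select]
    keep = [ds.feature_names[j] for j in top]
    leaked = TypedDataset(
        table=ds.table[keep + [ds.target]].copy(), target=ds.target
    )
    _, inspector = run_cross_validation(
        leaked,
        _noise_pipeline(),
        cv=cv or CVScheme(kind="stratified_kfold", k=5, seed=seed),
        metrics=["accuracy"],
        return_inspector=True,
        store_fold_models=False,
        seed=seed,
    )
    return count_correct(inspector)


def leakage_certification(
    n_seeds: int = 100,
    n: int = 400,
    p: int = 1000,
    n_select: int = 10,
    k: int = 5,
    level: float = 0.99,
    seed: int = 0,
) -> dict:
    """Run the paired chance/leak demonstration over ``n_seeds`` datasets.

    Clean half: the engine evaluates [zscore, svm] with 5-fold CV on
    pure-noise binary data; correct test predictions are pooled over all
    seeds and the pooled accuracy must lie inside the central ``level``
    binomial band around 0.5.  Leaky half: top-``n_select`` features
    chosen on all samples pre-split; the pooled accuracy's one-sided
    binomial p-value against 0.5 quantifies the (expected) rejection.
    """
    rng = np.random.default_rng(seed)
    probe_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    clean_correct = clean_total = 0
    leaky_correct = leaky_total = 0
    for s in probe_seeds:
        ds, _ = make_noise_probe(n=n, p=p, task="classification", seed=int(s))
        _, inspector = run_cross_validation(
            ds,
            _noise_pipeline(),
            cv=CVScheme(kind="stratified_kfold", k=k, seed=int(s)),
            metrics=["accuracy"],
            return_inspector=True,
            store_fold_models=False,
            seed=int(s),
        )
        c, t = count_correct(inspector)
        clean_correct += c
        clean_total += t
        c, t = leaky_topk_selection_cv(ds, n_select=n_select, seed=int(s))
        leaky_correct += c
        leaky_total += t
    band = binomial_chance_band(clean_total, level=level)
    clean_acc = clean_correct / clean_total
    leaky_acc = leaky_correct / leaky_total
    leaky_p = float(
        sps.binomtest(leaky_correct, leaky_total, 0.5, alternative="greater").pvalue
    )
    return {
        "clean_accuracy": clean_acc,
        "clean_in_band": bool(band[0] <= clean_acc <= band[1]),
        "band": band,
        "n_predictions": clean_total,
        "leaky_accuracy": leaky_acc,
        "leaky_binomial_p": leaky_p,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------

def nesting_certification(
    n_seeds: int = 100,
    n: int = 100,
    p: int = 20,
    k_candidates: tuple = (2, 5, 10),
    k: int = 5,
    metric: str = "accuracy",
    seed: int = 0,
) -> dict:
    """Tune-on-test vs nested-CV hyperparameter selection on noise data.

    The tuned hyperparameter is the size of a univariate feature
    selection feeding an SVM — candidates that are *exchangeable* under
    the null (each picks a different noise subset, so their fold scores
    differ only by noise; a hyperparameter with a deterministic ordering
    on noise would make both procedures agree trivially).  For each seed:
    (a) the OUTER-TEST-PICKED reference evaluates every candidate with
    the same outer CV and keeps the best mean score — tuning and
    estimating on the same test folds; (b) the engine runs the honestly
    nested search and reports its outer estimate.  On null data (a) is
    optimistically biased; a sign test over seeds quantifies it.
    """
    rng = np.random.default_rng(seed)
    probe_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    picked, nested = [], []
    for s in probe_seeds:
        ds, _ = make_noise_probe(n=n, p=p, task="classification", seed=int(s))
        scheme = CVScheme(k=k, seed=int(s))
        # (a) tune on the outer test folds: max over candidates of the
        # outer mean — the pitfall, implemented with the same engine runs
        candidate_means = []
        for kc in k_candidates:
            ps = PipelineSpec("classification").add("select_univariate", k=kc).add("svm")
            table = run_cross_validation(
                ds, ps, cv=scheme, metrics=[metric],
                store_fold_models=False, seed=int(s),
            )
            candidate_means.append(table["score"].mean())
        picked.append(max(candidate_means))
        # (b) honest nested search
        ps = (
            PipelineSpec("classification")
            .add("select_univariate", k=list(k_candidates))
            .add("svm")
        )
        table = run_cross_validation(
            ds, ps, cv=scheme, metrics=[metric],
            search=SearchSpec(tuning_metric=metric),
            store_fold_models=False, seed=int(s),
        )
        nested.append(table["score"].mean())
    picked = np.asarray(picked)
    nested = np.asarray(nested)
    wins = int((picked > nested).sum())
    p_sign = float(
        sps.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue
    )
    return {
        "mean_tune_on_test": float(picked.mean()),
        "mean_nested": float(nested.mean()),
        "mean_gap": float((picked - nested).mean()),
        "wins": wins,
        "n_seeds": n_seeds,
        "sign_test_p": p_sign,
    }


# ---------------------------------------------------------------------------

def corrected_ttest_calibration(
    n_sims: int = 2000,
    k: int = 5,
    repeats: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the corrected vs naive paired t-test under an
    exchangeable null with dependent folds.

    Per-fold score differences are simulated as compound-symmetric
    Gaussians with between-fold correlation rho = n_test/(n_test+n_train)
    = 1/k — the correlation structure the correction is derived for (and
    the regime where the naive test's inflation is at its textbook
    worst).  A shared dataset-level component sqrt(a)*g with
    a = rho/(1-rho) on top of unit fold noise realizes that correlation
    exactly.
    """
    from .stats import corrected_ttest

    rng = np.random.default_rng(seed)
    J = k * repeats
    ratio = 1.0 / (k - 1)
    rho = 1.0 / k
    a = rho / (1.0 - rho)
    # per-fold sizes on a notional n samples; only the ratio matters
    n_train, n_test = k - 1, 1
    rej_corrected = rej_naive = 0
    for _ in range(n_sims):
        d = np.sqrt(a) * rng.standard_normal() + rng.standard_normal(J)
        res = corrected_ttest(d, np.zeros(J), n_train=n_train, n_test=n_test)
        if res.p_value < alpha:
            rej_corrected += 1
        t_naive = d.mean() / np.sqrt(d.var(ddof=1) / J)
        p_naive = 2.0 * sps.t.sf(abs(t_naive), df=J - 1)
        if p_naive < alpha:
            rej_naive += 1
    return {
        "type_I_corrected": rej_corrected / n_sims,
        "type_I_naive": rej_naive / n_sims,
        "n_sims": n_sims,
        "alpha": alpha,
        "rho": rho,
    }


# ---------------------------------------------------------------------------

def misclassified_age_gap(ds: TypedDataset, inspector) -> float:
    """Welch t-test p-value for an age difference between misclassified
    cases and misclassified controls (pooled over folds and repeats).

    An age-driven classifier misclassifies atypically-aged participants
    (old controls, young cases), producing a significant gap; after
    honest confound removal the misclassifications are age-random and the
    gap vanishes.
    """
    preds = inspector.fold_predictions()
    wrong = preds[preds["y_true"] != preds["y_pred"]]
    age = ds.table["age"]
    ages_case = age.loc[wrong.loc[wrong["y_true"] == "case", "sample_id"]]
    ages_control = age.loc[wrong.loc[wrong["y_true"] == "control", "sample_id"]]
    if len(ages_case) < 2 or len(ages_control) < 2:
        return 1.0
    return float(sps.ttest_ind(ages_case, ages_control, equal_var=False).pvalue)


def confound_pattern_certification(
    n_seeds: int = 20,
    alpha: float = 1e-4,
    n: int = 498,
    p: int = 68,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Qualitative case/control contrast on confounded synthetic data.

    Per seed: classify with and without subgroup-trained (controls-only)
    confound removal; test the misclassified-participants age gap at
    ``alpha``.  The expected pattern — significant without removal,
    non-significant with — is counted over seeds.
    """
    rng = np.random.default_rng(seed)
    probe_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    hits_without = hits_with = hits_both = 0
    acc_without, acc_with = [], []
    for s in probe_seeds:
        s = int(s)
        ds, _ = make_confounded_data(n=n, p=p, seed=s)
        scheme = CVScheme(k=k, seed=s)
        # the age column is never a direct predictor in either arm: the
        # contrast is about age signal carried BY the features
        plain = (
            PipelineSpec("classification")
            .add("zscore", apply_to=all_except("confound"))
            .add("svm", apply_to=all_except("confound"))
        )
        t1, insp1 = run_cross_validation(
            ds, plain, cv=scheme, metrics=["accuracy"],
            return_inspector=True, store_fold_models=False, seed=s,
        )
        p_without = misclassified_age_gap(ds, insp1)
        removed = (
            PipelineSpec("classification")
            .add(
                "confound_removal",
                apply_to=all_except("confound"),
                subgroup=("diagnosis", ("control",)),
            )
            .add("zscore")
            .add("svm")
        )
        t2, insp2 = run_cross_validation(
            ds, removed, cv=scheme, metrics=["accuracy"],
            return_inspector=True, store_fold_models=False, seed=s,
        )
        p_with = misclassified_age_gap(ds, insp2)
        sig_without = p_without < alpha
        ns_with = p_with >= alpha
        hits_without += sig_without
        hits_with += ns_with
        hits_both += sig_without and ns_with
        acc_without.append(t1["score"].mean())
        acc_with.append(t2["score"].mean())
    return {
        "pattern_rate": hits_both / n_seeds,
        "significant_without_removal_rate": hits_without / n_seeds,
        "nonsignificant_with_removal_rate": hits_with / n_seeds,
        "mean_accuracy_without_removal": float(np.mean(acc_without)),
        "mean_accuracy_with_removal": float(np.mean(acc_with)),
        "n_seeds": n_seeds,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------

def cbpm_recovery(
    n_seeds: int = 50,
    n: int = 300,
    p_edges: int = 500,
    k_pos: int = 20,
    k_neg: int = 20,
    r: float = 0.4,
    threshold: float = 0.01,
    seed: int = 0,
) -> dict:
    """Selection recall and false-selection rate of the CBPM screen on
    planted edge data, averaged over seeds.

    Recall = fraction of planted edges selected into the matching-sign
    set; false-selection rate = fraction of null edges selected at all.
    At threshold alpha the expected false rate is alpha (raw per-feature
    screening, no multiplicity correction — by construction).
    """
    rng = np.random.default_rng(seed)
    probe_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    recalls, false_rates = [], []
    for s in probe_seeds:
        ds, truth = make_edge_data(
            n=n, p_edges=p_edges, k_pos=k_pos, k_neg=k_neg, r=r, seed=int(s)
        )
        model = fit_cbpm(ds.X, ds.y.to_numpy(), threshold=threshold, mode="both")
        pos_true, neg_true = set(truth["pos_set"]), set(truth["neg_set"])
        planted = pos_true | neg_true
        selected = set(model.pos_set) | set(model.neg_set)
        hit = len(pos_true & set(model.pos_set)) + len(neg_true & set(model.neg_set))
        recalls.append(hit / len(planted))
        nulls = p_edges - len(planted)
        false_rates.append(len(selected - planted) / nulls)
    return {
        "selection_recall": float(np.mean(recalls)),
        "false_selection_rate": float(np.mean(false_rates)),
        "n_seeds": n_seeds,
        "threshold": threshold,
    }
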