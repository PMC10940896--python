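"""The evaluation entry point: leakage-free (nested) cross-validation.

:func:`run_cross_validation` evaluates a compiled typed pipeline under an
outer CV scheme.  The leakage-freedom contract: for every outer split,
*every* fitted quantity — preprocessing statistics, PCA bases,
correlation-based selections, confound coefficients, and chosen
hyperparameters — is computed from the training partition only.  When a
step carries a hyperparameter grid, the search runs in an inner CV that
partitions only the outer-training data, and the outer test fold scores
the refit best configuration exactly once.

All metrics are reported in higher-is-better orientation (error metrics
negated), so score tables and comparisons compose without sign
bookkeeping.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import clone
from sklearn.impute._base import _BaseImputer
from sklearn.metrics import get_scorer, make_scorer
from sklearn.model_selection import (
    GridSearchCV,
    GroupKFold,
    KFold,
    LeaveOneOut,
    RandomizedSearchCV,
    RepeatedKFold,
    RepeatedStratifiedKFold,
    StratifiedKFold,
)

from .data_model import TypedDataset, decode_name
from .inspect import CVInspector, FoldRecord
from .pipeline import (
    ColumnScoped,
    CompiledPipeline,
    PipelineError,
    PipelineSpec,
    compile_pipeline,
)

__all__ = [
    "CVScheme",
    "SearchSpec",
    "CVError",
    "run_cross_validation",
    "nested_fit",
    "score",
    "available_metrics",
    "write_scores",
    "read_scores",
    "scores_fingerprint",
    "summarize_scores",
    "SCORES_COLUMNS",
]

SCORES_COLUMNS = [
    "model_label",
    "repeat_idx",
    "fold_idx",
    "metric_name",
    "score",
    "n_train",
    "n_test",
    "fit_time",
]

CV_KINDS = (
    "kfold",
    "repeated_kfold",
    "stratified_kfold",
    "group_kfold",
    "leave_one_out",
)


class CVError(ValueError):
    pass


@dataclass(frozen=True)
class CVScheme:
    """Outer (or inner) cross-validation scheme.

    ``k`` is ignored for leave-one-out; ``repeats`` > 1 upgrades kfold and
    stratified_kfold to their repeated variants.  ``seed`` feeds the
    shuffling; with ``shuffle=False`` folds are contiguous sample blocks.
    """

    kind: str = "kfold"
    k: int = 5
    repeats: int = 1
    shuffle: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        if self.kind not in CV_KINDS:
            raise CVError(f"cv kind must be one of {CV_KINDS}, got {self.kind!r}")
        if self.kind != "leave_one_out" and self.k < 2:
            raise CVError(f"need k >= 2 folds, got {self.k}")
        if self.repeats < 1:
            raise CVError(f"repeats must be >= 1, got {self.repeats}")

    def n_splits(self, n_samples: int) -> int:
        if self.kind == "leave_one_out":
            return n_samples
        return self.k * self.repeats

    def test_over_train(self, n_samples: int) -> float:
        """n_test/n_train implied by the scheme (fold-size jitter ignored)."""
        if self.kind == "leave_one_out":
            return 1.0 / (n_samples - 1)
        return 1.0 / (self.k - 1)

    def build(self, problem_type: str, has_groups: bool):
        if self.kind == "leave_one_out":
            return LeaveOneOut()
        if self.kind == "group_kfold":
            if not has_groups:
                raise CVError("group_kfold requires a groups column in the dataset")
            return GroupKFold(n_splits=self.k)
        seed = self.seed if self.shuffle else None
        if self.kind == "stratified_kfold":
            if problem_type != "classification":
                raise CVError("stratified CV requires a classification target")
            if self.repeats > 1:
                return RepeatedStratifiedKFold(
                    n_splits=self.k, n_repeats=self.repeats, random_state=self.seed
                )
            return StratifiedKFold(n_splits=self.k, shuffle=self.shuffle, random_state=seed)
        # kfold / repeated_kfold
        if self.repeats > 1 or self.kind == "repeated_kfold":
            return RepeatedKFold(
                n_splits=self.k, n_repeats=max(self.repeats, 1), random_state=self.seed
            )
        return KFold(n_splits=self.k, shuffle=self.shuffle, random_state=seed)

    def inner_default(self, seed: int) -> "CVScheme":
        """Inner scheme for nested search: propagate stratification and
        grouping inward, single repeat, 5 folds."""
        kind = {
            "stratified_kfold": "stratified_kfold",
            "group_kfold": "group_kfold",
        }.get(self.kind, "kfold")
        return CVScheme(kind=kind, k=5, repeats=1, shuffle=True, seed=seed)


@dataclass(frozen=True)
class SearchSpec:
    """Hyperparameter search configuration for the inner CV."""

    searcher: str = "grid"
    inner_cv: Optional[CVScheme] = None
    n_candidates: int = 10
    tuning_metric: Optional[str] = None

    def __post_init__(self):
        if self.searcher not in ("grid", "random"):
            raise CVError(f"searcher must be 'grid' or 'random', got {self.searcher!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _pearson_r(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return 0.0
    return float(sps.pearsonr(y_true, y_pred)[0])


_METRIC_SCORERS = {
    "accuracy": lambda: get_scorer("accuracy"),
    "balanced_accuracy": lambda: get_scorer("balanced_accuracy"),
    "roc_auc": lambda: get_scorer("roc_auc"),
    "f1": lambda: get_scorer("f1"),
    "r2": lambda: get_scorer("r2"),
    "neg_mae": lambda: get_scorer("neg_mean_absolute_error"),
    "neg_mse": lambda: get_scorer("neg_mean_squared_error"),
    "pearson_r": lambda: make_scorer(_pearson_r),
}


def available_metrics() -> list:
    return sorted(_METRIC_SCORERS)


def _scorer(name: str):
    if name not in _METRIC_SCORERS:
        raise CVError(
            f"unknown metric {name!r}; registered metrics: {available_metrics()}"
        )
    return _METRIC_SCORERS[name]()


def score(model, X, y, metric: str) -> float:
    """Score a fitted model; higher is always better (errors negated)."""
    return float(_scorer(metric)(model, X, y))


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def _derive_seed(master: int, stream: int) -> int:
    # counter-based substream: stable under parallel or serial execution
    return int(np.random.SeedSequence([master, stream]).generate_state(1)[0] % (2**31 - 1))


def _enumerate_splits(scheme: CVScheme, splitter, X, y, groups):
    n = len(X)
    for i, (train, test) in enumerate(splitter.split(X, y, groups)):
        if scheme.kind == "leave_one_out":
            repeat, fold = 0, i
        else:
            repeat, fold = divmod(i, scheme.k)
        yield repeat, fold, train, test


def _check_missing(X: pd.DataFrame, pipeline) -> None:
    if not X.isna().any().any():
        return
    has_imputer = any(
        isinstance(step, ColumnScoped) and isinstance(step.transformer, _BaseImputer)
        for _, step in pipeline.steps
    )
    if not has_imputer:
        bad = [decode_name(c)[0] for c in X.columns[X.isna().any()]]
        raise CVError(
            f"missing values in columns {bad} but the pipeline has no "
            "imputation step; add one (e.g. 'impute') or drop the rows"
        )


def _seed_estimators(pipeline, seed: int) -> None:
    """Fix every unset random_state in the pipeline to a seed-derived value."""
    params = pipeline.get_params(deep=True)
    updates = {
        key: _derive_seed(seed, 1 + i)
        for i, (key, value) in enumerate(sorted(params.items()))
        if key.endswith("random_state") and value is None
    }
    if updates:
        pipeline.set_params(**updates)


def nested_fit(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    compiled: CompiledPipeline,
    search: SearchSpec,
    seed: int,
    groups_train: Optional[np.ndarray] = None,
    outer_scheme: Optional[CVScheme] = None,
):
    """Run the inner search on an outer-training partition.

    Returns ``(best_params, refit_pipeline, inner_records)``.  The grid
    searcher enumerates the full cartesian product of the step grids; ties
    break by first-in-enumeration order; the best configuration is refit
    on the full outer-training partition.
    """
    if not compiled.needs_search:
        raise CVError("nested_fit requires a pipeline with a hyperparameter grid")
    inner_scheme = search.inner_cv
    if inner_scheme is None:
        base = outer_scheme or CVScheme()
        inner_scheme = base.inner_default(seed=seed)
    elif inner_scheme.seed is None:
        inner_scheme = replace(inner_scheme, seed=seed)
    problem_type = compiled.spec.problem_type
    inner = inner_scheme.build(problem_type, has_groups=groups_train is not None)
    tuning = search.tuning_metric or (
        "accuracy" if problem_type == "classification" else "r2"
    )
    common = dict(
        scoring=_scorer(tuning),
        cv=inner,
        refit=True,
        n_jobs=None,
        error_score=np.nan,
    )
    if search.searcher == "grid":
        searcher = GridSearchCV(clone(compiled.pipeline), compiled.param_grid, **common)
    else:
        searcher = RandomizedSearchCV(
            clone(compiled.pipeline),
            compiled.param_grid,
            n_iter=search.n_candidates,
            random_state=_derive_seed(seed, 997),
            **common,
        )
    fit_kwargs = {}
    if groups_train is not None and inner_scheme.kind == "group_kfold":
        fit_kwargs["groups"] = groups_train
    searcher.fit(X_train, y_train, **fit_kwargs)
    if np.all(np.isnan(searcher.cv_results_["mean_test_score"])):
        raise CVError("all hyperparameter candidates failed in the inner CV")
    inner_records = {
        "params": list(searcher.cv_results_["params"]),
        "mean_test_score": np.asarray(searcher.cv_results_["mean_test_score"]),
    }
    return searcher.best_params_, searcher.best_estimator_, inner_records


def _display_params(raw: dict) -> dict:
    """Full sklearn paths -> 'step.param' display names."""
    out = {}
    for key, value in raw.items():
        parts = key.split("__")
        if len(parts) >= 3 and parts[1] in ("transformer", "estimator"):
            out[f"{parts[0]}.{'__'.join(parts[2:])}"] = value
        else:
            out[".".join(parts)] = value
    return out


def _fixed_params(ps: PipelineSpec) -> dict:
    out = {}
    for step in ps.steps:
        for param, value in step.fixed.items():
            out[f"{step.step_name}.{param}"] = value
    return out


def run_cross_validation(
    ds: TypedDataset,
    ps: PipelineSpec,
    cv: Optional[CVScheme] = None,
    metrics: Optional[Sequence] = None,
    search: Optional[SearchSpec] = None,
    return_inspector: bool = False,
    return_models: bool = False,
    store_fold_models: bool = True,
    seed: int = 0,
):
    """Evaluate a pipeline spec under cross-validation.

    Returns a tidy scores DataFrame (one row per repeat x fold x metric),
    optionally followed by a :class:`CVInspector` and/or the list of
    fitted per-fold pipelines.  Determinism: identical
    ``(ds, ps, cv, seed)`` give an identical table (wall-clock
    ``fit_time`` aside; see :func:`scores_fingerprint`).
    """
    problem_type = ps.problem_type
    if metrics is None:
        metrics = ["accuracy"] if problem_type == "classification" else ["r2"]
    metrics = list(metrics)
    if not metrics:
        raise CVError("metrics must be non-empty")
    scorers = {m: _scorer(m) for m in metrics}

    if cv is None:
        cv = CVScheme(kind="kfold", k=5, repeats=1, shuffle=True, seed=seed)
    elif cv.seed is None and (cv.shuffle or cv.repeats > 1):
        cv = replace(cv, seed=seed)

    if ps.needs_search and search is None:
        search = SearchSpec()
    if search is not None and not ps.needs_search:
        search = None  # degenerate: nothing to search over

    compiled = compile_pipeline(ps, ds)
    X = compiled.encode(ds)
    y = ds.y.to_numpy()
    groups = None if ds.groups is None else ds.table[ds.groups].to_numpy()
    _check_missing(X, compiled.pipeline)
    _seed_estimators(compiled.pipeline, seed)

    classes = np.unique(y) if problem_type == "classification" else None
    splitter = cv.build(problem_type, has_groups=groups is not None)

    rows = []
    records = []
    fold_models = []
    label = ps.model_label
    fixed_display = _fixed_params(ps)
    for repeat, fold, train, test in _enumerate_splits(cv, splitter, X, y, groups):
        X_tr, X_te = X.iloc[train], X.iloc[test]
        y_tr, y_te = y[train], y[test]
        if classes is not None and len(np.unique(y_tr)) < len(classes):
            warnings.warn(
                f"repeat {repeat} fold {fold}: a class is absent from the "
                "training fold; fold skipped with NaN score",
                UserWarning,
                stacklevel=2,
            )
            for m in metrics:
                rows.append((label, repeat, fold, m, np.nan, len(train), len(test), np.nan))
            continue
        fold_seed = _derive_seed(seed, 104729 + repeat * 1000 + fold)
        t0 = time.perf_counter()
        if search is not None:
            gtr = None if groups is None else groups[train]
            best_raw, fitted, _ = nested_fit(
                X_tr, y_tr, compiled, search, seed=fold_seed,
                groups_train=gtr, outer_scheme=cv,
            )
            chosen = {**fixed_display, **_display_params(best_raw)}
        else:
            fitted = clone(compiled.pipeline)
            fitted.fit(X_tr, y_tr)
            chosen = dict(fixed_display)
        fit_time = time.perf_counter() - t0
        for m in metrics:
            try:
                value = float(scorers[m](fitted, X_te, y_te))
            except Exception as exc:  # e.g. roc_auc without decision scores
                raise CVError(f"metric {m!r} failed on repeat {repeat} fold {fold}: {exc}")
            rows.append((label, repeat, fold, m, value, len(train), len(test), fit_time))
        y_pred = fitted.predict(X_te)
        records.append(
            FoldRecord(
                repeat=repeat,
                fold=fold,
                train_ids=list(ds.sample_ids[train]),
                test_ids=list(ds.sample_ids[test]),
                y_true=np.asarray(y_te),
                y_pred=np.asarray(y_pred),
                chosen_params=chosen,
                model=fitted if (store_fold_models or return_models) else None,
            )
        )
        if return_models:
            fold_models.append(fitted)

    table = pd.DataFrame(rows, columns=SCORES_COLUMNS)
    table.attrs["cv"] = {
        "kind": cv.kind,
        "k": cv.k,
        "repeats": cv.repeats,
        "shuffle": cv.shuffle,
        "seed": cv.seed,
        "n_samples": len(ds.table),
        "test_over_train": cv.test_over_train(len(ds.table)),
    }
    table.attrs["model_label"] = label
    n_nan = int(table["score"].isna().sum())
    if n_nan:
        warnings.warn(
            f"{n_nan} NaN fold scores kept in the table (excluded from means)",
            UserWarning,
            stacklevel=2,
        )
    out = [table]
    if return_inspector:
        out.append(
            CVInspector(
                records=records,
                metrics=metrics,
                scheme=dict(table.attrs["cv"]),
                model_label=label,
                store_models=store_fold_models,
            )
        )
    if return_models:
        out.append(fold_models)
    return out[0] if len(out) == 1 else tuple(out)


# ---------------------------------------------------------------------------
# scores table I/O and summaries
# ---------------------------------------------------------------------------

def summarize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd per (model, metric); NaN folds excluded with a count."""
    def _agg(g):
        return pd.Series(
            {
                "mean": g["score"].mean(),
                "sd": g["score"].std(ddof=1),
                "n_folds": len(g),
                "n_nan": int(g["score"].isna().sum()),
            }
        )

    return (
        table.groupby(["model_label", "metric_name"])[["score"]]
        .apply(_agg)
        .reset_index()
    )


def write_scores(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a scores table as CSV or JSON-lines (schema = SCORES_COLUMNS)."""
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "jsonl":
        table.to_json(path, orient="records", lines=True)
    else:
        raise CVError(f"unknown scores format {format!r}")


def read_scores(path, format: str = "csv") -> pd.DataFrame:
    if format == "csv":
        table = pd.read_csv(path)
    elif format == "jsonl":
        table = pd.read_json(path, orient="records", lines=True)
    else:
        raise CVError(f"unknown scores format {format!r}")
    missing = [c for c in SCORES_COLUMNS if c not in table.columns]
    if missing:
        raise CVError(f"scores table at {path} lacks columns {missing}")
    return table[SCORES_COLUMNS]


def scores_fingerprint(table: pd.DataFrame) -> str:
    """Deterministic CSV serialization of everything but wall-clock time.

    Two runs with identical data, pipeline, scheme and seed produce
    byte-identical fingerprints.
    """
    det = table[[c for c in SCORES_COLUMNS if c != "fit_time"]]
    return det.to_csv(index=False, float_format="%.17g")
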