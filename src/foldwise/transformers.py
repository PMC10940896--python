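"""Confound regression and Connectome-Based Predictive Modelling (CBPM).

Both transformers are common in neuroimaging prediction workflows and both
are easy to get wrong in ways that leak test-set information; they are
implemented here as ordinary fit/transform components so the CV engine can
scope every fitted statistic to the training partition.

Confound regression
    Each feature is regressed (ordinary least squares) on the confound
    columns plus an intercept; the residual replaces the feature.  The
    regression may be *trained* on a subgroup of rows (e.g. only healthy
    controls) while the learned coefficients are applied to every row —
    the subgroup restricts fitting, never transforming.

CBPM
    Features are screened by univariate correlation with the target at a
    significance threshold alpha, split by correlation sign, aggregated
    (sum by default) into one or two summary features, and a linear
    read-out maps the aggregates to the target.  Selection p-values are
    deliberately NOT multiplicity-corrected: the method screens at a raw
    per-feature threshold, and the surrounding cross-validation is what
    protects the performance estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ConfoundRemover",
    "CBPM",
    "ConfoundRemoverModel",
    "CBPMModel",
    "fit_confound_remover",
    "remove_confounds",
    "fit_cbpm",
    "predict_cbpm",
    "correlation_screen",
]

_RIDGE_FALLBACK = 1e-8


# ======================================================================
# confound regression
# ======================================================================

@dataclass
class ConfoundRemoverModel:
    """Fitted per-feature OLS of feature on [1, confounds].

    ``coef_`` has shape (n_features, n_confounds + 1); column 0 is the
    intercept.  ``subgroup`` records the fitting restriction, if any.
    """

    feature_names: list
    confound_names: list
    coef_: np.ndarray
    subgroup: Optional[tuple] = None
    n_fit_rows: int = 0

    def predict_from_confounds(self, C: np.ndarray) -> np.ndarray:
        C = np.asarray(C, dtype=float)
        design = np.column_stack([np.ones(len(C)), C])
        return design @ self.coef_.T


def _solve_ols(design: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Least squares of each target column on the design; ridge fallback
    (penalty 1e-8) with a warning when the design is singular."""
    gram = design.T @ design
    if np.linalg.matrix_rank(gram) < design.shape[1]:
        warnings.warn(
            "singular confound design (collinear or constant confounds); "
            f"falling back to ridge with penalty {_RIDGE_FALLBACK}",
            UserWarning,
            stacklevel=3,
        )
        gram = gram + _RIDGE_FALLBACK * np.eye(design.shape[1])
        return np.linalg.solve(gram, design.T @ targets)
    beta, *_ = np.linalg.lstsq(design, targets, rcond=None)
    return beta


def fit_confound_remover(
    X,
    C,
    subgroup_mask: Optional[np.ndarray] = None,
    feature_names: Optional[Sequence] = None,
    confound_names: Optional[Sequence] = None,
) -> ConfoundRemoverModel:
    """Fit per-feature confound regressions.

    Parameters
    ----------
    X : (n, p) feature matrix (array or DataFrame)
    C : (n, q) confound matrix
    subgroup_mask : optional boolean vector restricting the *fitting* rows.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns) if feature_names is None else list(feature_names)
        X = X.to_numpy(dtype=float)
    if isinstance(C, pd.DataFrame):
        confound_names = list(C.columns) if confound_names is None else list(confound_names)
        C = C.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, p = X.shape
    q = C.shape[1]
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if confound_names is None:
        confound_names = [f"c{j}" for j in range(q)]
    if subgroup_mask is not None:
        subgroup_mask = np.asarray(subgroup_mask, dtype=bool)
        if subgroup_mask.sum() == 0:
            raise ValueError("confound-removal subgroup matches zero rows")
        Xf, Cf = X[subgroup_mask], C[subgroup_mask]
    else:
        Xf, Cf = X, C
    if len(Xf) < q + 2:
        raise ValueError(
            f"need at least n_confounds+2={q + 2} fitting rows, got {len(Xf)}"
        )
    design = np.column_stack([np.ones(len(Cf)), Cf])
    coef = _solve_ols(design, Xf).T  # (p, q+1)
    return ConfoundRemoverModel(
        feature_names=list(feature_names),
        confound_names=list(confound_names),
        coef_=coef,
        n_fit_rows=len(Xf),
    )


def remove_confounds(model: ConfoundRemoverModel, X, C) -> np.ndarray:
    """Residualize ALL rows of X against the fitted confound model.

    Column order of the output matches the input.  Note the asymmetry: a
    subgroup restricts fitting only — every row is transformed.
    """
    names = None
    index = None
    if isinstance(X, pd.DataFrame):
        unseen = [c for c in X.columns if c not in model.feature_names]
        if unseen:
            raise ValueError(f"unseen feature columns: {unseen}")
        names, index = list(X.columns), X.index
        X = X.to_numpy(dtype=float)
    if isinstance(C, pd.DataFrame):
        unseen = [c for c in C.columns if c not in model.confound_names]
        if unseen:
            raise ValueError(f"unseen confound columns: {unseen}")
        C = C.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    resid = X - model.predict_from_confounds(C)
    if names is not None:
        return pd.DataFrame(resid, columns=names, index=index)
    return resid


class ConfoundRemover(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around the per-feature confound regression.

    The CV pipeline machinery passes the confound columns (and an optional
    subgroup mask) to :meth:`fit` as fit parameters; standalone use goes
    through :func:`fit_confound_remover` / :func:`remove_confounds`.

    Parameters
    ----------
    subgroup:
        Optional ``(column, values)`` pair; rows whose value of ``column``
        is in ``values`` form the fitting subsample.  The column is looked
        up by the pipeline wrapper (it may be the target).
    """

    def __init__(self, subgroup=None):
        self.subgroup = subgroup

    def fit(self, X, y=None, confounds=None, subgroup_mask=None):
        if confounds is None:
            raise ValueError(
                "ConfoundRemover.fit requires confound columns; declare a "
                "'confound' feature type in the dataset"
            )
        self.model_ = fit_confound_remover(X, confounds, subgroup_mask=subgroup_mask)
        self.model_.subgroup = tuple(self.subgroup) if self.subgroup else None
        return self

    def transform(self, X, confounds=None):
        if confounds is None:
            raise ValueError("ConfoundRemover.transform requires confound columns")
        return remove_confounds(self.model_, X, confounds)

    def fitted_summary(self) -> dict:
        m = self.model_
        return {
            "n_features": len(m.feature_names),
            "n_confounds": len(m.confound_names),
            "n_fit_rows": m.n_fit_rows,
            "coef_l2_norm": float(np.linalg.norm(m.coef_)),
        }


# ======================================================================
# CBPM
# ======================================================================

def correlation_screen(X: np.ndarray, y: np.ndarray, method: str = "pearson"):
    """Per-feature correlation with the target and two-sided p-values.

    Vectorized Pearson (Spearman = Pearson on ranks); p-values from the
    exact t transform t = r*sqrt((n-2)/(1-r^2)) with n-2 dof.  Features
    with zero variance get r = 0, p = 1 and can never be selected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError(f"need n >= 4 samples for the correlation screen, got {n}")
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"corr_method must be 'pearson' or 'spearman', got {method!r}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    valid = denom > 0
    r = np.zeros(X.shape[1])
    np.divide(Xc.T @ yc, denom, out=r, where=valid)
    r = np.clip(r, -1.0, 1.0)
    p = np.ones_like(r)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df=n - 2)
    return r, p


_AGGS = {"sum": np.sum, "mean": np.mean}


@dataclass
class CBPMModel:
    """Fitted CBPM: selected edge sets plus the linear read-out.

    ``readout_coef_`` holds the intercept first, then one slope per used
    aggregate (positive first when both are used).  A model with no
    surviving features in any required set is ``degenerate`` and predicts
    the training target mean.
    """

    threshold: float
    corr_method: str
    mode: str
    agg: str
    feature_names: list
    pos_set: list
    neg_set: list
    used_sets: list  # subset of ["positive", "negative"], enumeration order
    readout_coef_: np.ndarray
    degenerate: bool
    y_mean_: float
    r_: np.ndarray = field(repr=False, default=None)
    p_: np.ndarray = field(repr=False, default=None)

    def aggregate(self, X) -> np.ndarray:
        """Per-sample aggregation over the training-selected sets."""
        if isinstance(X, pd.DataFrame):
            name_to_idx = {c: i for i, c in enumerate(X.columns)}
            X = X.to_numpy(dtype=float)
        else:
            name_to_idx = {c: i for i, c in enumerate(self.feature_names)}
            X = np.asarray(X, dtype=float)
        fn = _AGGS[self.agg]
        cols = []
        for which in self.used_sets:
            names = self.pos_set if which == "positive" else self.neg_set
            idx = [name_to_idx[c] for c in names]
            cols.append(fn(X[:, idx], axis=1))
        if not cols:
            return np.zeros((len(X), 0))
        return np.column_stack(cols)


def _select_sets(r, p, threshold, mode, feature_names):
    selected = p < threshold
    pos = [feature_names[j] for j in np.flatnonzero(selected & (r > 0))]
    neg = [feature_names[j] for j in np.flatnonzero(selected & (r < 0))]
    if mode == "positive":
        want = [("positive", pos)]
    elif mode == "negative":
        want = [("negative", neg)]
    elif mode == "both":
        want = [("positive", pos), ("negative", neg)]
    else:
        raise ValueError(f"mode must be positive/negative/both, got {mode!r}")
    used = [w for w, names in want if names]
    if mode == "both" and len(used) == 1:
        warnings.warn(
            f"CBPM mode='both' but only the {used[0]} set is non-empty; "
            "degrading to a single aggregate feature",
            UserWarning,
            stacklevel=3,
        )
    return pos, neg, used


def fit_cbpm(
    X,
    y,
    threshold: float = 0.01,
    corr_method: str = "pearson",
    mode: str = "both",
    agg: str = "sum",
) -> CBPMModel:
    """Screen, sign-split, aggregate and fit the linear read-out."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_names = [f"x{j}" for j in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float)
    if agg not in _AGGS:
        raise ValueError(f"agg must be one of {sorted(_AGGS)}, got {agg!r}")
    r, p = correlation_screen(Xv, y, corr_method)
    pos, neg, used = _select_sets(r, p, threshold, mode, feature_names)
    model = CBPMModel(
        threshold=threshold,
        corr_method=corr_method,
        mode=mode,
        agg=agg,
        feature_names=feature_names,
        pos_set=pos,
        neg_set=neg,
        used_sets=used,
        readout_coef_=np.array([float(np.mean(y))]),
        degenerate=not used,
        y_mean_=float(np.mean(y)),
        r_=r,
        p_=p,
    )
    if model.degenerate:
        warnings.warn(
            "CBPM selected no features at the given threshold; the model is "
            "degenerate and predicts the training target mean",
            UserWarning,
            stacklevel=2,
        )
        return model
    A = model.aggregate(pd.DataFrame(Xv, columns=feature_names))
    design = np.column_stack([np.ones(len(A)), A])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    model.readout_coef_ = beta
    return model


def predict_cbpm(model: CBPMModel, X) -> np.ndarray:
    """Aggregate with the TRAINING-selected sets and apply the read-out.

    No re-selection happens at prediction time.
    """
    n = len(X)
    if model.degenerate:
        return np.full(n, model.y_mean_)
    A = model.aggregate(X)
    return model.readout_coef_[0] + A @ model.readout_coef_[1:]


class CBPM(BaseEstimator, TransformerMixin):
    """Transformer form of CBPM: outputs the 1-2 aggregate summary columns.

    Follow it with a ``linear`` model step to obtain the classic CBPM
    predictor; the functional :func:`fit_cbpm` / :func:`predict_cbpm` pair
    bundles the read-out for direct use.
    """

    def __init__(self, threshold=0.01, corr_method="pearson", mode="both", agg="sum"):
        self.threshold = threshold
        self.corr_method = corr_method
        self.mode = mode
        self.agg = agg

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("CBPM is target-aware; fit requires y")
        self.model_ = fit_cbpm(
            X, y,
            threshold=self.threshold,
            corr_method=self.corr_method,
            mode=self.mode,
            agg=self.agg,
        )
        return self

    def transform(self, X):
        if self.model_.degenerate:
            # constant column so a downstream linear model predicts its intercept
            return np.zeros((len(X), 1))
        return self.model_.aggregate(X)

    def get_feature_names_out(self, input_features=None):
        if self.model_.degenerate:
            return np.array(["degenerate"])
        return np.array(list(self.model_.used_sets))

    def fitted_summary(self) -> dict:
        m = self.model_
        return {
            "n_pos_selected": len(m.pos_set),
            "n_neg_selected": len(m.neg_set),
            "degenerate": m.degenerate,
            "threshold": m.threshold,
        }
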