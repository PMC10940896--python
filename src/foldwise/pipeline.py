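"""Fluent construction of typed supervised pipelines.

A :class:`PipelineSpec` is an ordered list of steps — zero or more
transformers followed by exactly one model — where every step carries a
:class:`~foldwise.data_model.TypeSelector` saying *which feature columns it
touches* and an optional hyperparameter grid.  ``compile`` turns the spec
into a scikit-learn ``Pipeline`` whose transformer steps are wrapped in a
column-scoped applicator: selected columns are transformed, everything
else passes through bit-identical, and produced columns get deterministic
names (``step__original`` for one-to-one steps, ``step__k`` for
dimension-changing ones) plus a type label so later selectors can address
them.

Hyperparameters are attached with plain names at ``add`` time; the
compiler performs the step prefixing internally, so users never write
``step__param`` strings themselves.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.pipeline import Pipeline as SkPipeline

from . import registry as reg
from .data_model import (
    ALL,
    TypeSelector,
    TypedDataset,
    as_selector,
    decode_name,
    encode_name,
)
from .transformers import ConfoundRemover

__all__ = [
    "StepSpec",
    "PipelineSpec",
    "CompiledPipeline",
    "PipelineError",
    "compile_pipeline",
]

#: reserved type label for non-feature columns that must travel with the
#: data (e.g. a subgroup column for subgroup-trained confound removal);
#: wildcard selectors never match it
AUX_TYPE = "aux"


class PipelineError(ValueError):
    pass


def sel_matches(sel: TypeSelector, label: str) -> bool:
    """Selector match with the aux-label carve-out: wildcards skip aux."""
    if label == AUX_TYPE:
        return sel.labels is not None and AUX_TYPE in sel.labels
    return sel.matches(label)


@dataclass
class StepSpec:
    """One pipeline step: component + scope + hyperparameter grid."""

    step_name: str
    component: Union[str, object]
    role: str  # "transformer" | "model"
    apply_to: TypeSelector = ALL
    grid: dict = dc_field(default_factory=dict)  # param -> candidate list (>=2)
    fixed: dict = dc_field(default_factory=dict)  # param -> value
    transform_output_type: str = "continuous"
    keep_confounds: bool = False
    confound_label: str = "confound"


@dataclass
class PipelineSpec:
    """Ordered steps; immutable-style: ``add`` returns a new spec."""

    problem_type: str
    steps: list = dc_field(default_factory=list)

    def __post_init__(self):
        if self.problem_type not in reg.PROBLEM_TYPES:
            raise PipelineError(
                f"problem_type must be one of {reg.PROBLEM_TYPES}, "
                f"got {self.problem_type!r}"
            )

    # ------------------------------------------------------------------
    def add(
        self,
        component,
        apply_to=ALL,
        name: Optional[str] = None,
        output_type: Optional[str] = None,
        keep_confounds: bool = False,
        **params,
    ) -> "PipelineSpec":
        """Append a step and return the extended spec (fluent).

        ``params`` values that are *lists* with two or more entries become
        grid candidates (triggering nested search); scalars, tuples and
        singleton lists become fixed parameters.  (Tuples are deliberately
        not grids so structured values like ``subgroup=(column, values)``
        pass through unchanged.)
        """
        role = self._role_of(component)
        if self.steps and self.steps[-1].role == "model":
            raise PipelineError(
                "cannot add a step after the model; the model is always last"
            )
        step_name = name or self._default_name(component)
        existing = {s.step_name for s in self.steps}
        if step_name in existing:
            k = 2
            while f"{step_name}_{k}" in existing:
                k += 1
            new_name = f"{step_name}_{k}"
            warnings.warn(
                f"duplicate step name {step_name!r}; renamed to {new_name!r}",
                UserWarning,
                stacklevel=2,
            )
            step_name = new_name
        grid, fixed = {}, {}
        for key, value in params.items():
            if isinstance(value, list):
                if len(value) == 0:
                    raise PipelineError(f"empty candidate list for parameter {key!r}")
                if len(value) == 1:
                    fixed[key] = value[0]
                else:
                    grid[key] = list(value)
            else:
                fixed[key] = value
        step = StepSpec(
            step_name=step_name,
            component=component,
            role=role,
            apply_to=as_selector(apply_to),
            grid=grid,
            fixed=fixed,
            transform_output_type=output_type or "continuous",
            keep_confounds=keep_confounds,
        )
        return PipelineSpec(self.problem_type, [*self.steps, step])

    def _role_of(self, component) -> str:
        if isinstance(component, str):
            if (component, "model") in reg._REGISTRY:
                return "model"
            if (component, "transformer") in reg._REGISTRY:
                return "transformer"
            # raises with near-miss suggestions
            reg.resolve(component, "model", self.problem_type)
        if hasattr(component, "predict"):
            return "model"
        if hasattr(component, "transform"):
            return "transformer"
        raise PipelineError(
            f"component {component!r} is neither a registered name nor a "
            "fit/predict/transform object"
        )

    @staticmethod
    def _default_name(component) -> str:
        if isinstance(component, str):
            return component
        return type(component).__name__.lower()

    # ------------------------------------------------------------------
    @property
    def model_step(self) -> StepSpec:
        models = [s for s in self.steps if s.role == "model"]
        if len(models) != 1:
            raise PipelineError(
                f"a pipeline needs exactly one model step, found {len(models)}"
            )
        return models[0]

    @property
    def model_label(self) -> str:
        return self.model_step.step_name

    @property
    def needs_search(self) -> bool:
        return any(s.grid for s in self.steps)

    def validate(self) -> None:
        model = self.model_step
        if self.steps[-1] is not model:
            raise PipelineError("the model step must be last")

    # -- config (de)serialization --------------------------------------
    def to_config(self) -> dict:
        steps = []
        for s in self.steps:
            if not isinstance(s.component, str):
                raise PipelineError(
                    f"step {s.step_name!r} holds a user object and cannot be "
                    "serialized; register it by name first"
                )
            entry = {"step": s.component, "name": s.step_name}
            if not s.apply_to.is_wildcard:
                entry["apply_to"] = {
                    "labels": sorted(s.apply_to.labels) if s.apply_to.labels else "*",
                    "exclude": sorted(s.apply_to.exclude),
                }
            params = {**s.fixed, **s.grid}
            if params:
                entry["params"] = params
            if s.keep_confounds:
                entry["keep_confounds"] = True
            steps.append(entry)
        return {"problem_type": self.problem_type, "steps": steps}

    @classmethod
    def from_config(cls, cfg: dict) -> "PipelineSpec":
        ps = cls(cfg["problem_type"])
        for entry in cfg["steps"]:
            apply_to = ALL
            if "apply_to" in entry:
                a = entry["apply_to"]
                if isinstance(a, dict):
                    labels = a.get("labels", "*")
                    apply_to = TypeSelector(
                        None if labels == "*" else frozenset(labels),
                        frozenset(a.get("exclude", [])),
                    )
                else:
                    apply_to = as_selector(a)
            params = dict(entry.get("params", {}))
            if "subgroup" in params and isinstance(params["subgroup"], dict):
                sg = params["subgroup"]
                params["subgroup"] = (sg["column"], tuple(sg["values"]))
            ps = ps.add(
                entry["step"],
                apply_to=apply_to,
                name=entry.get("name"),
                output_type=entry.get("output_type"),
                keep_confounds=bool(entry.get("keep_confounds", False)),
                **params,
            )
        return ps


# ======================================================================
# column-scoped applicator
# ======================================================================

class ColumnScoped(BaseEstimator, TransformerMixin):
    """Applies a transformer to the type-selected columns of an encoded
    frame; all other columns pass through unchanged (exact equality).

    Works on internally *type-encoded* frames (``name__:type:__label``
    columns) so the schema travels through a vanilla sklearn Pipeline.
    """

    def __init__(
        self,
        transformer,
        apply_to=ALL,
        step_name="step",
        output_type="continuous",
        consume=None,
        drop_consumed=True,
        target_name=None,
    ):
        self.transformer = transformer
        self.apply_to = apply_to
        self.step_name = step_name
        self.output_type = output_type
        self.consume = consume  # selector for side-input columns (confounds)
        self.drop_consumed = drop_consumed
        self.target_name = target_name

    def _split_columns(self, X: pd.DataFrame):
        sel, cons = [], []
        for col in X.columns:
            _, label = decode_name(col)
            if sel_matches(self.apply_to, label):
                sel.append(col)
            elif self.consume is not None and sel_matches(self.consume, label):
                cons.append(col)
        return sel, cons

    def _decoded(self, X: pd.DataFrame, cols) -> pd.DataFrame:
        sub = X[cols].copy()
        sub.columns = [decode_name(c)[0] for c in cols]
        return sub

    def fit(self, X, y=None, **fit_params):
        if not isinstance(X, pd.DataFrame):
            raise PipelineError("typed pipelines operate on DataFrames")
        sel, cons = self._split_columns(X)
        if not sel:
            raise PipelineError(
                f"step {self.step_name!r}: selector {self.apply_to!r} matches "
                "no columns in the incoming frame"
            )
        self.selected_cols_ = sel
        self.consumed_cols_ = cons
        X_sel = self._decoded(X, sel)
        est = clone(self.transformer)
        if isinstance(est, ConfoundRemover):
            if not cons:
                raise PipelineError(
                    f"step {self.step_name!r}: confound removal requires "
                    "columns with the 'confound' type label"
                )
            C = self._decoded(X, cons)
            mask = self._subgroup_mask(est, X, y)
            est.fit(X_sel, y, confounds=C, subgroup_mask=mask)
        else:
            est.fit(X_sel, y)
        self.transformer_ = est
        self._set_output_names(X_sel)
        return self

    def _subgroup_mask(self, est: ConfoundRemover, X: pd.DataFrame, y):
        if not est.subgroup:
            return None
        column, values = est.subgroup
        values = list(np.atleast_1d(values))
        if self.target_name is not None and column == self.target_name:
            series = pd.Series(np.asarray(y))
        else:
            matches = [c for c in X.columns if decode_name(c)[0] == column]
            if not matches:
                raise PipelineError(
                    f"step {self.step_name!r}: subgroup column {column!r} is "
                    "neither the target nor present in the frame"
                )
            series = X[matches[0]]
        return series.isin(values).to_numpy()

    def _set_output_names(self, X_sel: pd.DataFrame):
        est = self.transformer_
        sel_names = list(X_sel.columns)
        if isinstance(est, ConfoundRemover):
            out_names = sel_names  # residualization is one-to-one
        else:
            width = np.asarray(est.transform(X_sel.iloc[:2])).shape[1]
            if width == len(sel_names):
                out_names = sel_names
            elif hasattr(est, "get_support"):
                support = est.get_support()
                out_names = [n for n, keep in zip(sel_names, support) if keep]
            else:
                out_names = [str(k) for k in range(width)]
        self.output_names_ = [
            encode_name(f"{self.step_name}__{n}", self.output_type) for n in out_names
        ]

    def transform(self, X):
        X_sel = self._decoded(X, self.selected_cols_)
        est = self.transformer_
        if isinstance(est, ConfoundRemover):
            C = self._decoded(X, self.consumed_cols_)
            produced = est.transform(X_sel, confounds=C)
        else:
            produced = est.transform(X_sel)
        produced = pd.DataFrame(
            np.asarray(produced), index=X.index, columns=self.output_names_
        )
        dropped = set(self.selected_cols_)
        if self.drop_consumed:
            dropped |= set(self.consumed_cols_)
        passthrough = [c for c in X.columns if c not in dropped]
        return pd.concat([X[passthrough], produced], axis=1)

    def fitted_summary(self) -> dict:
        est = self.transformer_
        if hasattr(est, "fitted_summary"):
            return est.fitted_summary()
        return generic_fitted_summary(est)


def generic_fitted_summary(est, max_values: int = 1000) -> dict:
    """Fallback describe hook: flatten small numeric learned attributes,
    summarize large ones by shape and norm."""
    out = {}
    for attr in sorted(vars(est)):
        if not attr.endswith("_") or attr.startswith("_"):
            continue
        value = getattr(est, attr)
        arr = None
        if isinstance(value, (int, float, np.integer, np.floating)):
            out[attr] = float(value)
            continue
        if isinstance(value, np.ndarray) and np.issubdtype(value.dtype, np.number):
            arr = value
        if arr is None:
            continue
        if arr.size == 1:
            out[attr] = float(arr.ravel()[0])
        elif arr.size <= max_values:
            for idx, value in np.ndenumerate(arr):
                key = ",".join(str(i) for i in idx)
                out[f"{attr}[{key}]"] = float(value)
        else:
            out[f"{attr}.shape"] = str(arr.shape)
            out[f"{attr}.l2_norm"] = float(np.linalg.norm(arr))
    return out


class TypedModel(BaseEstimator):
    """Final estimator wrapper: selects the model's feature columns from
    the encoded frame and converts to a plain numeric array."""

    def __init__(self, estimator, apply_to=ALL):
        self.estimator = estimator
        self.apply_to = apply_to

    def _select(self, X: pd.DataFrame):
        cols = [c for c in X.columns if sel_matches(self.apply_to, decode_name(c)[1])]
        if not cols:
            raise PipelineError("model step: selector matches no columns")
        return cols

    def fit(self, X, y=None, **fit_params):
        self.feature_cols_ = self._select(X)
        est = clone(self.estimator)
        est.fit(X[self.feature_cols_].to_numpy(dtype=float), y, **fit_params)
        self.estimator_ = est
        if hasattr(est, "classes_"):
            self.classes_ = est.classes_
        return self

    def _as_array(self, X):
        return X[self.feature_cols_].to_numpy(dtype=float)

    def predict(self, X):
        return self.estimator_.predict(self._as_array(X))

    def predict_proba(self, X):
        return self.estimator_.predict_proba(self._as_array(X))

    def decision_function(self, X):
        return self.estimator_.decision_function(self._as_array(X))

    def fitted_summary(self) -> dict:
        return generic_fitted_summary(self.estimator_)

    def __sklearn_tags__(self):
        return self.estimator.__sklearn_tags__()


# ======================================================================
# compilation
# ======================================================================

@dataclass
class CompiledPipeline:
    """A spec bound to a dataset schema: an sklearn Pipeline plus the
    parameter grid (full-path names) and encoding metadata."""

    spec: PipelineSpec
    pipeline: SkPipeline
    param_grid: dict
    target: Optional[str]
    aux_columns: list

    @property
    def needs_search(self) -> bool:
        return bool(self.param_grid)

    def encode(self, ds: TypedDataset) -> pd.DataFrame:
        """Type-encoded feature frame, plus any aux (non-feature) columns
        a step needs at fit time."""
        X = ds.encoded_X()
        for col in self.aux_columns:
            X[encode_name(col, AUX_TYPE)] = ds.table[col].to_numpy()
        return X

    def fit(self, ds: TypedDataset):
        self.pipeline.fit(self.encode(ds), ds.y.to_numpy())
        return self

    def predict(self, ds: TypedDataset):
        return self.pipeline.predict(self.encode(ds))


def _instantiate(step: StepSpec, problem_type: str):
    if isinstance(step.component, str):
        entry = reg.resolve(step.component, step.role, problem_type if step.role == "model" else None)
        est = entry.make(problem_type)
    else:
        est = clone(step.component)
    valid = est.get_params()
    for param, value in step.fixed.items():
        if param not in valid:
            raise PipelineError(
                f"step {step.step_name!r}: parameter {param!r} is not accepted "
                f"by {type(est).__name__} (valid: {sorted(valid)[:12]}...)"
            )
        est.set_params(**{param: value})
    for param in step.grid:
        if param not in valid:
            raise PipelineError(
                f"step {step.step_name!r}: grid parameter {param!r} is not "
                f"accepted by {type(est).__name__}"
            )
    return est


def _static_schema(ds: TypedDataset) -> dict:
    schema: dict = {}
    for name in ds.feature_names:
        label = ds.type_of(name)
        schema[label] = schema.get(label, 0) + 1
    return schema


def compile_pipeline(ps: PipelineSpec, ds: TypedDataset) -> CompiledPipeline:
    """Validate the spec against the dataset and build the sklearn object.

    Selector emptiness is checked here, at build time, against the
    statically propagated schema, so misconfigured pipelines fail before
    any data is split.
    """
    ps.validate()
    schema = _static_schema(ds)
    sk_steps = []
    param_grid: dict = {}
    aux_columns: list = []
    for step in ps.steps:
        est = _instantiate(step, ps.problem_type)
        if step.role == "model":
            wrapped = TypedModel(est, apply_to=step.apply_to)
            n_match = sum(v for k, v in schema.items() if sel_matches(step.apply_to, k))
            if n_match == 0:
                raise PipelineError(
                    f"model step {step.step_name!r}: selector matches no columns"
                )
            sk_steps.append((step.step_name, wrapped))
            prefix = f"{step.step_name}__estimator__"
        else:
            n_match = sum(v for k, v in schema.items() if sel_matches(step.apply_to, k))
            if n_match == 0:
                raise PipelineError(
                    f"step {step.step_name!r}: selector {step.apply_to!r} "
                    f"matches no columns (schema: {schema})"
                )
            consume = None
            if isinstance(est, ConfoundRemover):
                consume = TypeSelector(frozenset([step.confound_label]))
                if est.subgroup:
                    column = est.subgroup[0]
                    if (
                        column != ds.target
                        and column not in ds.feature_names
                    ):
                        if column not in ds.table.columns:
                            raise PipelineError(
                                f"subgroup column {column!r} not in the dataset"
                            )
                        aux_columns.append(column)
            wrapped = ColumnScoped(
                est,
                apply_to=step.apply_to,
                step_name=step.step_name,
                output_type=step.transform_output_type,
                consume=consume,
                drop_consumed=not step.keep_confounds,
                target_name=ds.target,
            )
            sk_steps.append((step.step_name, wrapped))
            # static schema update: selected labels replaced by output label
            new_schema: dict = {}
            for label, count in schema.items():
                if not sel_matches(step.apply_to, label):
                    if (
                        consume is not None
                        and sel_matches(consume, label)
                        and not step.keep_confounds
                    ):
                        continue  # consumed and dropped
                    new_schema[label] = new_schema.get(label, 0) + count
            new_schema[step.transform_output_type] = (
                new_schema.get(step.transform_output_type, 0) + n_match
            )
            schema = new_schema
            prefix = f"{step.step_name}__transformer__"
        for param, candidates in step.grid.items():
            param_grid[f"{prefix}{param}"] = list(candidates)
    return CompiledPipeline(
        spec=ps,
        pipeline=SkPipeline(sk_steps),
        param_grid=param_grid,
        target=ds.target,
        aux_columns=sorted(set(aux_columns)),
    )
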