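"""Post-hoc transparency for CV runs.

:class:`CVInspector` exposes, for every (repeat, fold): the fitted
pipeline, the train/test sample ids, the test predictions, the chosen
hyperparameters (from nested search, or the fixed values), and fitted
parameter summaries via per-component describe hooks.
:func:`preprocess_until` replays a *fitted* pipeline's transformers up to
a named step so intermediate representations (z-scored features, PCA
scores, confound residuals, ...) can be examined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import TypedDataset, decode_columns
from .pipeline import ColumnScoped, CompiledPipeline, TypedModel

__all__ = [
    "FoldRecord",
    "CVInspector",
    "InspectError",
    "preprocess_until",
    "fold_predictions",
    "fold_params",
]


class InspectError(ValueError):
    pass


@dataclass
class FoldRecord:
    """Everything retained about one outer fold."""

    repeat: int
    fold: int
    train_ids: list
    test_ids: list
    y_true: np.ndarray
    y_pred: np.ndarray
    chosen_params: dict = field(default_factory=dict)
    model: Optional[object] = None  # fitted pipeline (or search refit)


def _fitted_pipeline(model):
    """Unwrap a search object to its refit best pipeline if needed."""
    return getattr(model, "best_estimator_", model)


@dataclass
class CVInspector:
    """Fold-wise view of a finished CV run."""

    records: list
    metrics: list
    scheme: dict
    model_label: str
    store_models: bool = True

    @property
    def n_folds(self) -> int:
        return len(self.records)

    def fold_model(self, repeat: int, fold: int):
        for rec in self.records:
            if rec.repeat == repeat and rec.fold == fold:
                if rec.model is None:
                    raise InspectError(
                        "fold models were not stored (summaries-only run)"
                    )
                return _fitted_pipeline(rec.model)
        raise InspectError(f"no record for repeat {repeat}, fold {fold}")

    @property
    def fold_index_map(self) -> dict:
        return {
            (rec.repeat, rec.fold): {"train": rec.train_ids, "test": rec.test_ids}
            for rec in self.records
        }

    # ------------------------------------------------------------------
    def fold_predictions(self) -> pd.DataFrame:
        """Long table: one row per (repeat, fold, test sample)."""
        frames = []
        for rec in self.records:
            frames.append(
                pd.DataFrame(
                    {
                        "repeat_idx": rec.repeat,
                        "fold_idx": rec.fold,
                        "sample_id": rec.test_ids,
                        "y_true": rec.y_true,
                        "y_pred": rec.y_pred,
                        "role": "test",
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["repeat_idx", "fold_idx", "sample_id", "y_true", "y_pred", "role"]
            )
        return pd.concat(frames, ignore_index=True)

    def prediction_summary(self) -> pd.DataFrame:
        """Per-sample mean/sd of predictions across repeats."""
        preds = self.fold_predictions()
        return (
            preds.groupby("sample_id")["y_pred"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"std": "sd", "count": "n_appearances"})
        )

    # ------------------------------------------------------------------
    def fold_params(self, include_fitted: bool = True) -> pd.DataFrame:
        """Tidy table (repeat, fold, step, param, value).

        Hyperparameters chosen per fold (or fixed values), plus — when the
        fold models were stored — fitted-parameter summaries from each
        component's describe hook (e.g. CBPM selected-set sizes, confound
        coefficient norms, PCA explained variance).
        """
        rows = []
        for rec in self.records:
            for key, value in rec.chosen_params.items():
                step, _, param = key.partition(".")
                rows.append((rec.repeat, rec.fold, step, param, value))
            if include_fitted and rec.model is not None:
                pipe = _fitted_pipeline(rec.model)
                for name, step in pipe.steps:
                    if not hasattr(step, "fitted_summary"):
                        continue
                    for key, value in step.fitted_summary().items():
                        rows.append((rec.repeat, rec.fold, name, key, value))
        return pd.DataFrame(
            rows, columns=["repeat_idx", "fold_idx", "step", "param", "value"]
        )


# module-level op aliases matching the functional surface
def fold_predictions(insp: CVInspector) -> pd.DataFrame:
    return insp.fold_predictions()


def fold_params(insp: CVInspector) -> pd.DataFrame:
    return insp.fold_params()


# ---------------------------------------------------------------------------

def preprocess_until(fitted, ds: TypedDataset, step_name: str) -> pd.DataFrame:
    """Apply a fitted pipeline's transformers up to and including
    ``step_name`` and return the intermediate table with clean names.

    ``fitted`` may be a fitted :class:`CompiledPipeline`, a fitted sklearn
    pipeline produced by the engine, or a search object wrapping one.
    """
    if isinstance(fitted, CompiledPipeline):
        X = fitted.encode(ds)
        pipe = _fitted_pipeline(fitted.pipeline)
    else:
        pipe = _fitted_pipeline(fitted)
        # rebuild the encoded frame the way the engine did
        compiled_like = [s for _, s in pipe.steps if isinstance(s, ColumnScoped)]
        X = ds.encoded_X()
        needed = set()
        for s in compiled_like:
            needed.update(getattr(s, "consumed_cols_", []))
            needed.update(getattr(s, "selected_cols_", []))
        missing_aux = [c for c in needed if c not in X.columns]
        for col in missing_aux:
            from .data_model import decode_name

            raw, _ = decode_name(col)
            if raw in ds.table.columns:
                X[col] = ds.table[raw].to_numpy()
    names = [name for name, _ in pipe.steps]
    if step_name not in names:
        raise InspectError(
            f"unknown step {step_name!r}; available steps: {names}"
        )
    for name, step in pipe.steps:
        if isinstance(step, TypedModel) or not hasattr(step, "transform"):
            raise InspectError(
                f"step {step_name!r} is the model; use predict instead of "
                "preprocess_until"
            )
        X = step.transform(X)
        if name == step_name:
            break
    return decode_columns(X)
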