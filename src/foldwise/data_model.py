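"""Typed tabular data container.

A :class:`TypedDataset` is a plain pandas DataFrame plus column *roles*:
which column is the prediction target, which columns are features, an
optional grouping column for grouped cross-validation, and a *type map*
assigning each feature column exactly one type label (``"continuous"``,
``"categorical"``, ``"confound"``, or any user-defined label).  Pipeline
steps later address feature subsets through these labels, which is what
makes selective preprocessing (standardize only continuous columns,
residualize only against confounds, ...) expressible without leaking
column bookkeeping into user code.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TYPE",
    "TypedDataset",
    "TypeSelector",
    "ALL",
    "all_except",
    "load_table",
    "write_table",
    "assign_types",
    "select_columns",
]

#: type label given to feature columns not mentioned in a type map
DEFAULT_TYPE = "continuous"

# separator used internally to encode "column__:type:__label" names when a
# typed frame travels through an sklearn pipeline; never user-visible
TYPE_SEP = "__:type:__"


class DataModelError(ValueError):
    """Raised for violated typed-dataset invariants."""


@dataclass(frozen=True)
class TypeSelector:
    """Selects feature columns by their type label.

    ``labels=None`` is the wildcard: all feature columns.  ``exclude``
    removes labels from the wildcard or from ``labels``.
    """

    labels: Optional[frozenset] = None
    exclude: frozenset = frozenset()

    def __post_init__(self):
        if self.labels is not None:
            labels = frozenset(self.labels)
            if not labels:
                raise DataModelError("TypeSelector labels must be non-empty or None (wildcard)")
            object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "exclude", frozenset(self.exclude))

    @property
    def is_wildcard(self) -> bool:
        return self.labels is None and not self.exclude

    def matches(self, label: str) -> bool:
        if label in self.exclude:
            return False
        return self.labels is None or label in self.labels

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.labels is None and not self.exclude:
            return "TypeSelector(*)"
        inc = "*" if self.labels is None else "{" + ",".join(sorted(self.labels)) + "}"
        exc = f" - {{{','.join(sorted(self.exclude))}}}" if self.exclude else ""
        return f"TypeSelector({inc}{exc})"


#: wildcard selector: every feature column
ALL = TypeSelector()


def all_except(*labels: str) -> TypeSelector:
    """Wildcard selector minus the given type labels (e.g. all but confounds)."""
    return TypeSelector(labels=None, exclude=frozenset(labels))


def as_selector(sel: Union[TypeSelector, str, Iterable[str], None]) -> TypeSelector:
    """Coerce a string, iterable of labels, ``"*"`` or None into a TypeSelector."""
    if sel is None:
        return ALL
    if isinstance(sel, TypeSelector):
        return sel
    if isinstance(sel, str):
        return ALL if sel == "*" else TypeSelector(frozenset([sel]))
    return TypeSelector(frozenset(sel))


@dataclass
class TypedDataset:
    """Samples-by-columns table with column roles.

    Parameters
    ----------
    table:
        The data; column names must be unique, the row index supplies
        sample identifiers (must be unique).
    target:
        Name of the target column.  Never a feature.
    feature_names:
        Ordered predictor columns.  Defaults to every column except the
        target and the grouping column.
    type_map:
        label -> list of feature names.  Features absent from every list
        get :data:`DEFAULT_TYPE`.  A feature may carry exactly one label.
    groups:
        Optional name of a grouping column for grouped CV; not a feature.
    """

    table: pd.DataFrame
    target: Optional[str] = None
    feature_names: Optional[list] = None
    type_map: dict = field(default_factory=dict)
    groups: Optional[str] = None

    def __post_init__(self):
        cols = list(self.table.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise DataModelError(f"duplicate column names: {dupes}")
        if not self.table.index.is_unique:
            raise DataModelError("sample_ids (row index) must be unique")
        if self.target is not None and self.target not in cols:
            raise DataModelError(f"target column {self.target!r} not in table")
        if self.groups is not None and self.groups not in cols:
            raise DataModelError(f"groups column {self.groups!r} not in table")
        if self.feature_names is None:
            drop = {self.target, self.groups}
            self.feature_names = [c for c in cols if c not in drop]
        else:
            self.feature_names = list(self.feature_names)
            missing = [c for c in self.feature_names if c not in cols]
            if missing:
                raise DataModelError(f"feature columns not in table: {missing}")
        if self.target is not None and self.target in self.feature_names:
            raise DataModelError(f"target {self.target!r} may not be a feature")
        if self.groups is not None and self.groups in self.feature_names:
            raise DataModelError(f"groups column {self.groups!r} may not be a feature")
        self.type_map = _complete_type_map(self.type_map, self.feature_names)

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def X(self) -> pd.DataFrame:
        return self.table[self.feature_names]

    @property
    def y(self) -> pd.Series:
        if self.target is None:
            raise DataModelError("dataset has no target column assigned")
        return self.table[self.target]

    @property
    def group_values(self) -> Optional[pd.Series]:
        return None if self.groups is None else self.table[self.groups]

    def type_of(self, column: str) -> str:
        for label, names in self.type_map.items():
            if column in names:
                return label
        raise KeyError(column)

    def columns_of_type(self, label: str) -> list:
        return list(self.type_map.get(label, []))

    @property
    def column_types(self) -> dict:
        """feature name -> type label, in feature order."""
        out = {}
        for name in self.feature_names:
            out[name] = self.type_of(name)
        return out

    def encoded_X(self) -> pd.DataFrame:
        """Feature frame with type labels encoded into the column names.

        Internal representation used when handing data to an sklearn
        pipeline so the schema travels with the frame.
        """
        X = self.X.copy()
        X.columns = [f"{c}{TYPE_SEP}{self.type_of(c)}" for c in self.feature_names]
        return X

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        counts = {k: len(v) for k, v in self.type_map.items() if v}
        return (
            f"TypedDataset(n={self.n_samples}, features={len(self.feature_names)}, "
            f"types={counts}, target={self.target!r}, groups={self.groups!r})"
        )


def _complete_type_map(type_map: Mapping, feature_names: Sequence) -> dict:
    """Validate a partial type map and fill unlisted features with the default."""
    seen: dict = {}
    for label, names in type_map.items():
        if isinstance(names, str):
            names = [names]
        for name in names:
            if name not in feature_names:
                raise DataModelError(
                    f"type map names non-feature column {name!r} (label {label!r})"
                )
            if name in seen and seen[name] != label:
                raise DataModelError(
                    f"column {name!r} assigned two type labels: "
                    f"{seen[name]!r} and {label!r}"
                )
            seen[name] = label
    out: dict = {}
    for name in feature_names:
        label = seen.get(name, DEFAULT_TYPE)
        out.setdefault(label, []).append(name)
    return out


# -- column-name encoding helpers (used by the pipeline machinery) --------

def encode_name(name: str, label: str) -> str:
    return f"{name}{TYPE_SEP}{label}"


def decode_name(encoded: str) -> tuple:
    """Return (name, label) from an internal encoded column name."""
    if TYPE_SEP in encoded:
        name, label = encoded.rsplit(TYPE_SEP, 1)
        return name, label
    return encoded, DEFAULT_TYPE


def decode_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Strip internal type annotations from a frame's column names."""
    out = frame.copy()
    out.columns = [decode_name(c)[0] for c in frame.columns]
    return out


# -- I/O -------------------------------------------------------------------

_SEPS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in _SEPS:
            raise DataModelError(f"unknown table format {format!r}; use 'csv' or 'tsv'")
        return format
    return "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"


def load_table(path, format: Optional[str] = None) -> TypedDataset:
    """Read a delimited table into an untyped :class:`TypedDataset`.

    All columns come back as features with the default type; use
    :func:`assign_types` to designate target/confounds/groups.  Numeric
    columns are parsed as numbers, everything else is kept as categorical
    strings.  Ragged rows and duplicate header names are rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    sep = _SEPS[fmt]
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise DataModelError(f"{path}: empty file") from None
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise DataModelError(f"{path}: duplicate header names {dupes}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise DataModelError(
                    f"{path}: ragged row at line {lineno}: "
                    f"expected {len(header)} fields, got {len(row)}"
                )
    df = pd.read_csv(path, sep=sep)
    # non-numeric columns stay as plain strings (categorical)
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].astype(str).where(df[col].notna(), other=np.nan)
    return TypedDataset(table=df)


def write_table(ds: TypedDataset, path, format: Optional[str] = None) -> None:
    """Write the underlying table as CSV/TSV (canonical text form, no index)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    ds.table.to_csv(path, sep=_SEPS[fmt], index=False)


def assign_types(
    ds: TypedDataset,
    type_map: Optional[Mapping] = None,
    target: Optional[str] = None,
    groups: Optional[str] = None,
) -> TypedDataset:
    """Return a new dataset with column roles assigned.

    ``type_map`` is label -> column names; unmentioned feature columns
    keep the default label.  ``target`` and ``groups`` columns are removed
    from the feature set.
    """
    target = target if target is not None else ds.target
    groups = groups if groups is not None else ds.groups
    cols = list(ds.table.columns)
    drop = {target, groups}
    feature_names = [c for c in cols if c not in drop]
    if type_map:
        for label, names in type_map.items():
            if isinstance(names, str):
                names = [names]
            for name in names:
                if name not in cols:
                    raise DataModelError(f"type map names unknown column {name!r}")
                if name == target:
                    raise DataModelError(
                        f"target column {target!r} may not be listed as a feature"
                    )
    return TypedDataset(
        table=ds.table,
        target=target,
        feature_names=feature_names,
        type_map=dict(type_map or {}),
        groups=groups,
    )


def select_columns(ds: TypedDataset, sel: Union[TypeSelector, str, Iterable[str]]) -> list:
    """Resolve a type selector to an ordered list of feature column names.

    Order follows ``feature_names``.  An empty resolution raises, because
    a pipeline step scoped to nothing is a configuration error.
    """
    sel = as_selector(sel)
    out = [c for c in ds.feature_names if sel.matches(ds.type_of(c))]
    if not out:
        raise DataModelError(f"selector {sel!r} matches no feature columns")
    return out
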