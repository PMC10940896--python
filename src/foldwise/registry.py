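"""Name -> component resolution.

Models and transformers are addressed by short names (``"svm"``,
``"zscore"``, ``"cbpm"`` ...).  For models the same name resolves to a
different estimator depending on the problem type — ``"svm"`` is a
support-vector *regressor* under ``problem_type="regression"`` and a
support-vector *classifier* under ``"classification"`` — so callers never
import estimator classes themselves.  Any object honoring the de-facto
fit/predict/transform + get_params/set_params protocol can be registered.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Callable, Optional

__all__ = [
    "ComponentEntry",
    "RegistryError",
    "OptionalDependencyError",
    "resolve",
    "register",
    "registered_names",
]

PROBLEM_TYPES = ("regression", "classification")
ROLES = ("model", "transformer")


class RegistryError(KeyError):
    """Unknown name, role mismatch, or invalid registration."""

    def __str__(self):  # KeyError quotes its message; show it verbatim
        return self.args[0] if self.args else ""


class OptionalDependencyError(RegistryError):
    """A registered name that requires an optional extra not installed."""


@dataclass
class ComponentEntry:
    """One resolvable component.

    ``factory(problem_type, **params)`` must return an object supporting
    ``fit``; models additionally ``predict``, transformers ``transform``.
    ``problem_types`` limits which problem types the entry serves
    (``{"both"}`` means any, and is what transformers normally use).
    """

    name: str
    role: str
    factory: Callable
    problem_types: frozenset = frozenset({"both"})
    default_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise RegistryError(f"role must be one of {ROLES}, got {self.role!r}")
        self.problem_types = frozenset(self.problem_types)
        bad = self.problem_types - set(PROBLEM_TYPES) - {"both"}
        if bad:
            raise RegistryError(f"unknown problem types {sorted(bad)}")

    def covers(self, problem_type: Optional[str]) -> bool:
        if "both" in self.problem_types or problem_type is None:
            return True
        return problem_type in self.problem_types

    def make(self, problem_type: Optional[str] = None, **params):
        """Instantiate the component for the given problem type."""
        merged = {**self.default_params, **params}
        return self.factory(problem_type, **merged)


_REGISTRY: dict = {}


def register(entry: ComponentEntry, overwrite: bool = False) -> None:
    """Add a component; (name, role) must be unique unless overwriting."""
    key = (entry.name, entry.role)
    if key in _REGISTRY and not overwrite:
        raise RegistryError(
            f"{entry.role} {entry.name!r} is already registered; pass overwrite=True"
        )
    _validate_protocol(entry)
    _REGISTRY[key] = entry


def _validate_protocol(entry: ComponentEntry) -> None:
    """Instantiate a probe and check the fit/predict/transform contract."""
    probe_type = next(iter(entry.problem_types & set(PROBLEM_TYPES)), "regression")
    try:
        probe = entry.factory(probe_type, **entry.default_params)
    except OptionalDependencyError:
        return  # availability is checked at resolve time instead
    if not hasattr(probe, "fit"):
        raise RegistryError(f"{entry.role} {entry.name!r}: factory output lacks fit")
    if entry.role == "model" and not hasattr(probe, "predict"):
        raise RegistryError(f"model {entry.name!r}: factory output lacks predict")
    if entry.role == "transformer" and not hasattr(probe, "transform"):
        raise RegistryError(f"transformer {entry.name!r}: factory output lacks transform")


def resolve(name: str, role: str, problem_type: Optional[str] = None) -> ComponentEntry:
    """Look up a component by name and role, checking problem-type fit."""
    if role == "model" and problem_type is not None and problem_type not in PROBLEM_TYPES:
        raise RegistryError(
            f"problem_type must be one of {PROBLEM_TYPES}, got {problem_type!r}"
        )
    entry = _REGISTRY.get((name, role))
    if entry is None:
        candidates = [n for (n, r) in _REGISTRY if r == role]
        near = difflib.get_close_matches(name, candidates, n=3)
        hint = f"; did you mean {near}?" if near else ""
        raise RegistryError(f"unknown {role} {name!r}{hint}")
    if not entry.covers(problem_type):
        raise RegistryError(
            f"{role} {name!r} does not support problem_type={problem_type!r} "
            f"(supports {sorted(entry.problem_types)})"
        )
    if entry.factory is _rvr_factory:
        _rvr_available()  # raises OptionalDependencyError when absent
    return entry


def registered_names(role: Optional[str] = None) -> list:
    return sorted(n for (n, r) in _REGISTRY if role is None or r == role)


# -- built-in components ---------------------------------------------------

def _svm(problem_type, **p):
    from sklearn.svm import SVC, SVR

    return SVR(**p) if problem_type == "regression" else SVC(**p)


def _rf(problem_type, **p):
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    cls = RandomForestRegressor if problem_type == "regression" else RandomForestClassifier
    return cls(**p)


def _linear(problem_type, **p):
    from sklearn.linear_model import LinearRegression, LogisticRegression

    if problem_type == "regression":
        return LinearRegression(**p)
    return LogisticRegression(**p)


def _ridge(problem_type, **p):
    from sklearn.linear_model import Ridge, RidgeClassifier

    return Ridge(**p) if problem_type == "regression" else RidgeClassifier(**p)


def _logit(problem_type, **p):
    from sklearn.linear_model import LogisticRegression

    return LogisticRegression(**p)


def _gauss(problem_type, **p):
    from sklearn.gaussian_process import (
        GaussianProcessClassifier,
        GaussianProcessRegressor,
    )

    cls = GaussianProcessRegressor if problem_type == "regression" else GaussianProcessClassifier
    return cls(**p)


def _dummy(problem_type, **p):
    from sklearn.dummy import DummyClassifier, DummyRegressor

    return DummyRegressor(**p) if problem_type == "regression" else DummyClassifier(**p)


def _rvr_available():
    raise OptionalDependencyError(
        "model 'rvr' (relevance vector regression) requires an optional extra "
        "providing an RVM implementation, which is not installed; register a "
        "compatible estimator under the name 'rvr' to use it"
    )


def _rvr_factory(problem_type, **p):  # pragma: no cover - unreachable when absent
    _rvr_available()


def _zscore(problem_type, **p):
    from sklearn.preprocessing import StandardScaler

    return StandardScaler(**p)


def _variance_threshold(problem_type, **p):
    from sklearn.feature_selection import VarianceThreshold

    return VarianceThreshold(**p)


def _pca(problem_type, **p):
    from sklearn.decomposition import PCA

    return PCA(**p)


def _select_univariate(problem_type, **p):
    from sklearn.feature_selection import (
        SelectKBest,
        f_classif,
        f_regression,
    )

    p.setdefault("score_func", f_regression if problem_type == "regression" else f_classif)
    return SelectKBest(**p)


def _onehot(problem_type, **p):
    from sklearn.preprocessing import OneHotEncoder

    p.setdefault("handle_unknown", "ignore")
    p.setdefault("sparse_output", False)
    return OneHotEncoder(**p)


def _impute(problem_type, **p):
    from sklearn.impute import SimpleImputer

    return SimpleImputer(**p)


def _confound_removal(problem_type, **p):
    from .transformers import ConfoundRemover

    return ConfoundRemover(**p)


def _cbpm(problem_type, **p):
    from .transformers import CBPM

    return CBPM(**p)


_BUILTINS = [
    ComponentEntry("svm", "model", _svm, frozenset(PROBLEM_TYPES)),
    ComponentEntry("rf", "model", _rf, frozenset(PROBLEM_TYPES)),
    ComponentEntry("linear", "model", _linear, frozenset(PROBLEM_TYPES)),
    ComponentEntry("ridge", "model", _ridge, frozenset(PROBLEM_TYPES)),
    ComponentEntry("logit", "model", _logit, frozenset({"classification"})),
    ComponentEntry("gauss", "model", _gauss, frozenset(PROBLEM_TYPES)),
    ComponentEntry("dummy", "model", _dummy, frozenset(PROBLEM_TYPES)),
    ComponentEntry("rvr", "model", _rvr_factory, frozenset({"regression"})),
    ComponentEntry("zscore", "transformer", _zscore),
    ComponentEntry("variance_threshold", "transformer", _variance_threshold),
    ComponentEntry("pca", "transformer", _pca),
    ComponentEntry("select_univariate", "transformer", _select_univariate),
    ComponentEntry("onehot", "transformer", _onehot),
    ComponentEntry("impute", "transformer", _impute),
    ComponentEntry("confound_removal", "transformer", _confound_removal),
    ComponentEntry("cbpm", "transformer", _cbpm),
]

for _entry in _BUILTINS:
    _REGISTRY[(_entry.name, _entry.role)] = _entry
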