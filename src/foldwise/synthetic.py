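"""Synthetic fixture generators with known ground truth.

Each generator is a pure function of its parameters (seed included) and
returns a :class:`~foldwise.data_model.TypedDataset` together with a
ground-truth record, so every downstream check can compare against the
generating process rather than against stored constants.

The generators emulate the statistical structure of three recurring
neuroimaging prediction designs: a linear brain-feature -> continuous
outcome regression, a confounded case/control classification where an
age-like nuisance variable differs between groups, and a
vectorized-connectome design with edge features planted to correlate
with a continuous score.  A pure-noise probe with a guaranteed-null
generative process supports leakage certification.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .data_model import TypedDataset, assign_types

__all__ = [
    "make_regression_data",
    "make_confounded_data",
    "make_edge_data",
    "make_noise_probe",
    "vectorize_symmetric",
    "n_unique_edges",
]


def make_regression_data(
    n: int = 200,
    p: int = 10,
    k_informative: int = 5,
    beta_scale: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Linear regression data: y = X[, informative] @ beta + eps.

    Returns ``(dataset, truth)`` where ``truth`` holds the full
    coefficient vector (zeros on uninformative columns) and the
    informative index set.
    """
    if k_informative > p:
        raise ValueError(f"k_informative={k_informative} exceeds p={p}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    informative = np.arange(k_informative)
    beta[informative] = beta_scale * rng.standard_normal(k_informative)
    y = X @ beta + noise_sd * rng.standard_normal(n)
    cols = [f"x{j}" for j in range(p)]
    table = pd.DataFrame(X, columns=cols)
    table["y"] = y
    ds = TypedDataset(table=table, target="y")
    truth = {
        "beta": beta,
        "informative": informative,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return ds, truth


def make_confounded_data(
    n: int = 498,
    p: int = 68,
    confound_effect: float = 1.0,
    group_specific_slopes: float = 0.0,
    case_fraction: float = 0.5,
    target_effect: float = 0.0,
    noise_sd: float = 1.0,
    age_shift: float = 6.0,
    seed: int = 0,
):
    """Case/control data whose features carry an age (confound) signal.

    Structure: a binary diagnosis target, an ``age`` confound whose
    distribution is shifted by ``age_shift`` years between groups (so a
    classifier can exploit age alone), and ``p`` features

        x_ij = target_effect * t_i + gamma_i * z(age_i) + eps_ij

    with gamma_i = confound_effect for controls and
    confound_effect * (1 + group_specific_slopes) for cases — a nonzero
    slope difference makes subgroup-trained and full-sample confound
    fitting distinguishable.  Default sizes mirror a typical clinical
    cohort (about 500 participants, 68 region-level features).
    """
    if not 0.0 < case_fraction < 1.0:
        raise ValueError(f"case_fraction must be in (0,1), got {case_fraction}")
    rng = np.random.default_rng(seed)
    n_case = int(round(n * case_fraction))
    is_case = np.zeros(n, dtype=bool)
    is_case[rng.permutation(n)[:n_case]] = True
    t = is_case.astype(float)
    age = np.where(
        is_case,
        rng.normal(70.0 + age_shift, 8.0, size=n),
        rng.normal(70.0, 8.0, size=n),
    )
    z_age = (age - age.mean()) / age.std()
    gamma_row = confound_effect * (1.0 + group_specific_slopes * t)
    X = (
        target_effect * t[:, None]
        + gamma_row[:, None] * z_age[:, None]
        + noise_sd * rng.standard_normal((n, p))
    )
    cols = [f"f{j}" for j in range(p)]
    table = pd.DataFrame(X, columns=cols)
    table["age"] = age
    table["diagnosis"] = np.where(is_case, "case", "control")
    ds = TypedDataset(table=table, target="diagnosis")
    ds = assign_types(ds, type_map={"confound": ["age"]}, target="diagnosis")
    truth = {
        "is_case": is_case,
        "gamma_control": confound_effect,
        "gamma_case": confound_effect * (1.0 + group_specific_slopes),
        "target_effect": target_effect,
        "age_shift": age_shift,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return ds, truth


def make_edge_data(
    n: int = 300,
    p_edges: int = 500,
    k_pos: int = 20,
    k_neg: int = 20,
    r: float = 0.4,
    seed: int = 0,
):
    """Edge features with planted population correlation +-r to y.

    The planting uses the exact construction x = r*z_y + sqrt(1-r^2)*z,
    with z_y the standardized target and z independent noise, giving
    population correlation exactly r (sign-flipped for the negative set);
    remaining edges are independent noise.
    """
    if k_pos + k_neg > p_edges:
        raise ValueError("k_pos + k_neg must not exceed p_edges")
    if not 0.0 <= r < 1.0:
        raise ValueError(f"r must be in [0, 1), got {r}")
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    z_y = (y - y.mean()) / y.std()
    X = rng.standard_normal((n, p_edges))
    pos_idx = np.arange(k_pos)
    neg_idx = np.arange(k_pos, k_pos + k_neg)
    root = np.sqrt(1.0 - r**2)
    X[:, pos_idx] = r * z_y[:, None] + root * X[:, pos_idx]
    X[:, neg_idx] = -r * z_y[:, None] + root * X[:, neg_idx]
    cols = [f"e{j}" for j in range(p_edges)]
    table = pd.DataFrame(X, columns=cols)
    table["score"] = y
    ds = TypedDataset(table=table, target="score")
    truth = {
        "pos_set": [cols[j] for j in pos_idx],
        "neg_set": [cols[j] for j in neg_idx],
        "r": r,
        "seed": seed,
    }
    return ds, truth


def make_noise_probe(
    n: int = 400,
    p: int = 20,
    task: str = "classification",
    seed: int = 0,
):
    """Pure-noise probe: the target is independent of every feature.

    For classification the labels are exactly balanced (n // 2 per class,
    order shuffled).  Any leakage-free evaluation must score at chance on
    this data; scoring reliably above chance certifies a leak.
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"task must be classification or regression, got {task!r}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if task == "classification":
        y = np.zeros(n, dtype=int)
        y[: n // 2] = 1
        y = y[rng.permutation(n)]
    else:
        y = rng.standard_normal(n)
    cols = [f"x{j}" for j in range(p)]
    table = pd.DataFrame(X, columns=cols)
    table["target"] = y
    ds = TypedDataset(table=table, target="target")
    truth = {"task": task, "seed": seed, "null": True}
    return ds, truth


# ---------------------------------------------------------------------------

def n_unique_edges(m: int) -> int:
    """Unique off-diagonal edges of a symmetric m x m matrix: m(m-1)/2."""
    return m * (m - 1) // 2


def vectorize_symmetric(mat: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major order.

    This is the standard vectorization of a connectivity matrix: the
    diagonal and the redundant half are discarded so only unique edges
    remain (m parcels -> m(m-1)/2 features).
    """
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, equal_nan=True):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]
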