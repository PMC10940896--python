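"""Model comparison over a shared cross-validation.

Fold scores from a CV are not independent: every pair of folds shares
most of its training data, so the naive paired t-test on per-fold score
differences is anticonservative (its type-I error can exceed 40% where
5% is nominal).  The corrected resampled t-test inflates the variance of
the mean difference by the train/test overlap factor:

    t = mean(d) / sqrt( (1/J + n_test/n_train) * var(d) )

with ``d`` the per-fold score differences, ``J`` the number of shared
folds, ``var`` the unbiased sample variance, and Student's t with J-1
degrees of freedom for the two-sided p-value.  The correction follows the
classic variance-inflation argument: fold estimates behave approximately
as exchangeable variables with between-fold correlation
rho = n_test/(n_test + n_train); substituting that correlation into the
variance of the mean of J correlated terms and estimating the residual
variance by var(d) yields exactly the (1/J + n_test/n_train) factor.
For repeated k-fold, n_test/n_train = 1/(k-1) is taken from the scheme,
not from per-fold counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "StatsError",
    "corrected_ttest",
    "pairwise_compare",
    "plot_scores",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonResult:
    """Corrected paired comparison of two models on identical folds."""

    model_a: str
    model_b: str
    mean_diff: float
    t_stat: float
    p_value: float
    dof: int

    def swapped(self) -> "ComparisonResult":
        return ComparisonResult(
            self.model_b, self.model_a, -self.mean_diff, -self.t_stat,
            self.p_value, self.dof,
        )


def corrected_ttest(
    scores_a: Sequence,
    scores_b: Sequence,
    n_train: int,
    n_test: int,
    model_a: str = "a",
    model_b: str = "b",
) -> ComparisonResult:
    """Fold-dependency-corrected paired t-test.

    ``scores_a`` and ``scores_b`` must be aligned by (repeat, fold) and
    come from the same CV partitions; ``n_train``/``n_test`` set the
    overlap correction (for k-fold use the scheme's per-fold sizes, i.e.
    a ratio of 1/(k-1)).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("score vectors must be 1-D and the same length")
    J = len(a)
    if J < 2:
        raise StatsError(f"need at least 2 shared folds, got {J}")
    if n_train <= 0 or n_test <= 0:
        raise StatsError("n_train and n_test must be positive")
    d = a - b
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    factor = 1.0 / J + n_test / n_train
    if var == 0.0:
        if mean == 0.0:
            t = 0.0
            p = 1.0
        else:
            warnings.warn(
                "zero variance with non-zero mean difference: t is infinite",
                UserWarning,
                stacklevel=2,
            )
            t = np.inf if mean > 0 else -np.inf
            p = 0.0
    else:
        t = mean / np.sqrt(factor * var)
        p = float(2.0 * sps.t.sf(abs(t), df=J - 1))
    return ComparisonResult(
        model_a=model_a,
        model_b=model_b,
        mean_diff=mean,
        t_stat=float(t),
        p_value=p,
        dof=J - 1,
    )


# ---------------------------------------------------------------------------

def _fold_frame(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = table[table["metric_name"] == metric]
    if sub.empty:
        raise StatsError(f"metric {metric!r} not present in a scores table")
    return sub.sort_values(["repeat_idx", "fold_idx"]).reset_index(drop=True)


def _overlap_ratio(table: pd.DataFrame) -> float:
    """n_test/n_train from the scheme when known, else from fold counts."""
    cv = table.attrs.get("cv")
    if cv:
        if cv.get("kind") == "leave_one_out":
            return 1.0 / (cv["n_samples"] - 1)
        if cv.get("k"):
            return 1.0 / (cv["k"] - 1)
    return float((table["n_test"] / table["n_train"]).mean())


def _check_same_folds(fa: pd.DataFrame, fb: pd.DataFrame, la: str, lb: str) -> None:
    key = ["repeat_idx", "fold_idx", "n_train", "n_test"]
    if len(fa) != len(fb) or not fa[key].reset_index(drop=True).equals(
        fb[key].reset_index(drop=True)
    ):
        raise StatsError(
            f"models {la!r} and {lb!r} were not evaluated on identical CV "
            "partitions; comparison is undefined"
        )


def pairwise_compare(
    tables: Sequence[pd.DataFrame],
    metric: Optional[str] = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Corrected t-tests for all unordered model pairs.

    Every table must come from the *same* CV scheme and seed (identical
    (repeat, fold, n_train, n_test) structure); folds where either model
    has a NaN score are dropped pairwise.
    """
    if isinstance(tables, pd.DataFrame):
        groups = [g for _, g in tables.groupby("model_label", sort=False)]
        attrs = tables.attrs
        tables = []
        for g in groups:
            g = g.reset_index(drop=True)
            g.attrs = dict(attrs)
            tables.append(g)
    tables = list(tables)
    if len(tables) < 2:
        raise StatsError("need at least two models to compare")
    labels = []
    for t in tables:
        ls = t["model_label"].unique()
        if len(ls) != 1:
            raise StatsError("each table must hold exactly one model label")
        labels.append(ls[0])
    if len(set(labels)) != len(labels):
        raise StatsError(f"duplicate model labels: {labels}")
    seeds = {t.attrs.get("cv", {}).get("seed") for t in tables if t.attrs.get("cv")}
    if len(seeds) > 1:
        raise StatsError(
            "scores tables come from different CV seeds; comparison is undefined"
        )
    if metric is None:
        metric = tables[0]["metric_name"].iloc[0]
    results = []
    for (ta, la), (tb, lb) in itertools.combinations(zip(tables, labels), 2):
        fa, fb = _fold_frame(ta, metric), _fold_frame(tb, metric)
        _check_same_folds(fa, fb, la, lb)
        ok = fa["score"].notna().to_numpy() & fb["score"].notna().to_numpy()
        n_train = int(fa["n_train"].iloc[0])
        ratio = _overlap_ratio(ta)
        res = corrected_ttest(
            fa["score"].to_numpy()[ok],
            fb["score"].to_numpy()[ok],
            n_train=n_train,
            n_test=max(1, round(ratio * n_train)),
            model_a=la,
            model_b=lb,
        )
        results.append(res)
    out = pd.DataFrame(
        {
            "model_a": [r.model_a for r in results],
            "model_b": [r.model_b for r in results],
            "mean_diff": [r.mean_diff for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_value": [r.p_value for r in results],
            "dof": [r.dof for r in results],
        }
    )
    out.attrs["metric"] = metric
    if bonferroni:
        m = len(out)
        out["p_bonferroni"] = np.minimum(1.0, out["p_value"] * m)
    return out


# ---------------------------------------------------------------------------

def _corrected_ci(scores: np.ndarray, ratio: float, level: float = 0.95):
    """Mean +- t-quantile * corrected SE (same variance inflation as the test)."""
    scores = scores[~np.isnan(scores)]
    J = len(scores)
    mean = scores.mean()
    if J < 2:
        return mean, mean, mean
    se = np.sqrt((1.0 / J + ratio) * scores.var(ddof=1))
    half = sps.t.ppf(0.5 + level / 2, df=J - 1) * se
    return mean, mean - half, mean + half


def plot_scores(
    tables: Sequence[pd.DataFrame],
    comparisons: Optional[pd.DataFrame] = None,
    metric: Optional[str] = None,
    path=None,
):
    """Static scores figure: one column of fold dots per model, the mean
    with a corrected 95% CI bar, and (optionally) the pairwise stats
    table underneath.  Rendering is deterministic: fixed jitter seed and
    stable SVG ids, so identical input yields identical files.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise StatsError("need at least one scores table to plot")
    if metric is None:
        metric = tables[0]["metric_name"].iloc[0]
    with plt.rc_context({"svg.hashsalt": "foldwise"}):
        n_rows = 2 if comparisons is not None else 1
        fig, axes = plt.subplots(
            n_rows, 1, figsize=(1.8 + 1.6 * len(tables), 4.5 if n_rows == 1 else 6.5),
            gridspec_kw=None if n_rows == 1 else {"height_ratios": [3, 1]},
        )
        ax = axes if n_rows == 1 else axes[0]
        rng = np.random.default_rng(0)  # fixed: deterministic jitter
        for i, table in enumerate(tables):
            sub = _fold_frame(table, metric)
            label = sub["model_label"].iloc[0]
            scores = sub["score"].to_numpy()
            x = i + rng.uniform(-0.12, 0.12, size=len(scores))
            ax.plot(x, scores, "o", alpha=0.55, markersize=5, zorder=2)
            mean, lo, hi = _corrected_ci(scores, _overlap_ratio(table))
            ax.hlines(mean, i - 0.22, i + 0.22, color="black", zorder=3)
            ax.vlines(i, lo, hi, color="black", zorder=3)
            ax.annotate(
                label, (i, 0), xycoords=("data", "axes fraction"),
                xytext=(0, -18), textcoords="offset points", ha="center",
            )
        ax.set_xticks([])
        ax.set_xlim(-0.6, len(tables) - 0.4)
        ax.set_ylabel(metric)
        ax.set_title("fold scores (dots), mean and corrected 95% CI (bars)")
        if comparisons is not None:
            axt = axes[1]
            axt.axis("off")
            cell_text = [
                [
                    row["model_a"],
                    row["model_b"],
                    f"{row['mean_diff']:.4g}",
                    f"{row['t_stat']:.3f}",
                    f"{row['p_value']:.3g}",
                ]
                for _, row in comparisons.iterrows()
            ]
            axt.table(
                cellText=cell_text,
                colLabels=["model A", "model B", "mean diff", "t (corrected)", "p"],
                loc="center",
            )
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, metadata=_stable_metadata(str(path)))
            plt.close(fig)
            return None
        return fig


def _stable_metadata(path: str) -> dict:
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return {}
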