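"""Metrics and inferential comparisons for the classifier benchmark.

AUC is the primary metric (Mann-Whitney concordance with ties counted
half).  Cross-condition model comparison uses the Friedman rank test with
the Nemenyi critical difference as post-hoc; paired AUC comparisons on a
shared test set use DeLong's placement-value test with Benjamini-Hochberg
false-discovery-rate correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (ties counted half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics at a fixed score threshold.

    Returns f1, precision, recall (sensitivity), specificity; when nothing
    is predicted positive, precision is reported as 0 with
    ``precision_undefined`` flagged.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = tp / (tp + fn)
    specificity = tn / (tn + fp)
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return {
        "f1": f1,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "precision_undefined": undefined,
    }


@dataclass
class RankResult:
    """Friedman test with Nemenyi critical-difference post-hoc."""

    mean_ranks: pd.Series
    statistic: float
    p_value: float
    critical_difference: float
    significant: pd.DataFrame  # pairwise |mean-rank difference| >= CD


def friedman_rank(auc_matrix: pd.DataFrame, alpha: float = 0.05) -> RankResult:
    """Rank models across conditions and test for overall differences.

    Rows are conditions, columns are models.  Higher AUC gets the better
    (lower) rank; ties are averaged.  The Nemenyi critical difference is
    CD = q_alpha * sqrt(k (k + 1) / (6 N)).
    """
    df = pd.DataFrame(auc_matrix)
    if df.isna().any().any():
        raise ValueError("Friedman ranking requires a complete conditions x models table")
    N, k = df.shape
    if N < 2 or k < 2:
        raise ValueError("need at least 2 conditions and 2 models")
    ranks = df.rank(axis=1, ascending=False)
    mean_ranks = ranks.mean(axis=0)
    rbar = mean_ranks.to_numpy()
    # chi-square form with tie correction via scipy when possible
    if np.allclose(df.to_numpy().std(axis=1), 0):
        statistic, p_value = 0.0, 1.0
    else:
        statistic, p_value = stats.friedmanchisquare(
            *[df.iloc[:, j].to_numpy() for j in range(k)]
        )
    q_alpha = stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2)
    cd = float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * N)))
    diff = np.abs(rbar[:, None] - rbar[None, :])
    significant = pd.DataFrame(diff >= cd, index=df.columns, columns=df.columns)
    np.fill_diagonal(significant.values, False)
    return RankResult(
        mean_ranks=mean_ranks,
        statistic=float(statistic),
        p_value=float(p_value),
        critical_difference=cd,
        significant=significant,
    )


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    variance: float
    z: float
    p_value: float
    fdr_adjusted_p: float | None = None


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # midrank-based placements
    order = np.concatenate([pos, neg])
    ranks_all = stats.rankdata(order)
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """Two-sided DeLong test comparing two correlated AUCs on paired scores."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores and labels must be paired on identical samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if np.isclose(diff, 0):
            return DelongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(auc_a, auc_b, float(var), float(z), p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def overfit_delta(rows: pd.DataFrame) -> pd.Series:
    """Mean (train AUC - test AUC) per architecture over conditions."""
    df = pd.DataFrame(rows)
    required = {"arch", "train_auc", "test_auc"}
    if not required.issubset(df.columns):
        raise ValueError(f"rows must have columns {sorted(required)}")
    if df[["train_auc", "test_auc"]].isna().any().any():
        raise ValueError("unmatched train/test rows")
    return df.groupby("arch").apply(
        lambda g: (g["train_auc"] - g["test_auc"]).mean(), include_groups=False
    )


def auc_pivot(rows: pd.DataFrame, value: str = "test_auc") -> pd.DataFrame:
    """Fold-averaged conditions x models AUC table for Friedman ranking."""
    df = pd.DataFrame(rows)
    agg = df.groupby(["cohort_id", "arch"])[value].mean().reset_index()
    return agg.pivot(index="cohort_id", columns="arch", values=value)


def critical_difference_plot(result: RankResult, path=None):
    """Render a critical-difference diagram of mean ranks (SVG/PNG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranks = result.mean_ranks.sort_values()
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(ranks) + 1.5))
    y = np.arange(len(ranks))
    ax.scatter(ranks.to_numpy(), y, zorder=3)
    best = ranks.iloc[0]
    ax.axvspan(best, best + result.critical_difference, alpha=0.15, label="CD from best")
    for yi, (name, r) in zip(y, ranks.items()):
        ax.text(r, yi + 0.15, f"{name} ({r:.2f})", fontsize=8)
    ax.set_yticks([])
    ax.set_xlabel("mean rank (lower is better)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
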