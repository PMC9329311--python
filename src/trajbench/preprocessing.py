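"""Cohort preprocessing: imputation, normalization, partitioning.

The workflow mirrors routine clinical time-series preparation: gaps are
filled by last observation carried forward (LOCF; backward for a missing
head, LOCB), cohorts are split 70/30 into train+validation and test strata
(stratified by class), and normalization statistics are computed on the
training partition only so no test information leaks into the features.
Z-scoring is the default; min-max rescaling to [-1, 1] is used for the
angular-field image encoder, whose arccos transform requires that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np

from trajbench.cohort_simulator import Cohort


def locf_impute(series: np.ndarray) -> np.ndarray:
    """Last observation carried forward; leading gaps carried backward.

    Accepts one series or a matrix of series (NaN = missing); every row must
    have at least one observed value.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float)).copy()
    if np.isnan(x).all(axis=1).any():
        raise ValueError("cannot impute an all-missing series")
    n, T = x.shape
    obs = ~np.isnan(x)
    # forward fill: index of most recent observed column, -1 before the first
    idx = np.where(obs, np.arange(T)[None, :], -1)
    idx = np.maximum.accumulate(idx, axis=1)
    first = obs.argmax(axis=1)
    rows = np.arange(n)[:, None]
    filled = x[rows, np.where(idx >= 0, idx, first[:, None])]
    return filled[0] if np.asarray(series).ndim == 1 else filled


@dataclass
class SplitCohort:
    """A cohort partitioned for model development.

    ``train_idx`` and ``test_idx`` partition the cohort 70/30 (stratified by
    class); ``folds`` are cross-validation folds over the training portion;
    ``tuning_idx`` flags the 20% of training samples reserved for
    hyperparameter search; ``balanced_train_idx`` is the training partition
    after majority-class down-sampling (validation/test keep their natural
    imbalance).
    """

    cohort: Cohort
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[np.ndarray]
    tuning_idx: np.ndarray
    balanced_train_idx: np.ndarray

    @property
    def fold_count(self) -> int:
        return len(self.folds)

    def fold_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) index arrays for one cross-validation fold.

        Training indices are balanced by majority down-sampling; validation
        is the held-out fold with natural class proportions.
        """
        val = self.folds[fold]
        val_set = set(val.tolist())
        train = np.array([i for i in self.balanced_train_idx if i not in val_set])
        return train, val

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_idx": self.train_idx.tolist(),
                "test_idx": self.test_idx.tolist(),
                "folds": [f.tolist() for f in self.folds],
                "tuning_idx": self.tuning_idx.tolist(),
                "balanced_train_idx": self.balanced_train_idx.tolist(),
            }
        )


def partition(
    cohort: Cohort,
    fold_count: int = 3,
    tuning_fraction: float = 0.2,
    test_fraction: float = 0.3,
    seed: int = 0,
    balance_training: bool = True,
) -> SplitCohort:
    """Stratified 70/30 train+validation/test split with k folds over training."""
    labels = cohort.labels
    for cls in (0, 1):
        if (labels == cls).sum() < 10:
            raise ValueError("need at least 10 samples per class to partition")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_test = int(round(test_fraction * len(idx)))
        test_parts.append(idx[:n_test])
        train_parts.append(idx[n_test:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))

    # k folds over the training portion, stratified; fold_count == 1 degrades
    # to a single 25% validation holdout
    eff_folds = 4 if fold_count == 1 else fold_count
    folds: list[list[int]] = [[] for _ in range(eff_folds)]
    for cls in (0, 1):
        idx = rng.permutation(train_idx[labels[train_idx] == cls])
        for f, chunk in enumerate(np.array_split(idx, eff_folds)):
            folds[f].extend(chunk.tolist())
    fold_arrays = [np.sort(np.array(f, dtype=int)) for f in folds]
    if fold_count == 1:
        fold_arrays = fold_arrays[:1]

    shuffled = rng.permutation(train_idx)
    tuning_idx = np.sort(shuffled[: int(round(tuning_fraction * len(train_idx)))])

    if balance_training:
        counts = {c: (labels[train_idx] == c).sum() for c in (0, 1)}
        minority = min(counts, key=counts.get)
        majority = 1 - minority
        maj_idx = train_idx[labels[train_idx] == majority]
        keep_maj = rng.choice(maj_idx, size=counts[minority], replace=False)
        balanced = np.sort(
            np.concatenate([train_idx[labels[train_idx] == minority], keep_maj])
        )
    else:
        balanced = train_idx
    return SplitCohort(
        cohort=cohort,
        train_idx=train_idx,
        test_idx=test_idx,
        folds=fold_arrays,
        tuning_idx=tuning_idx,
        balanced_train_idx=balanced,
    )


@dataclass
class Normalizer:
    """Per-time-point affine normalization fit on training rows only."""

    kind: str  # "zscore" or "minmax"
    center: np.ndarray
    scale: np.ndarray
    target_range: tuple[float, float] = (-1.0, 1.0)

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "zscore":
            return (x - self.center) / self.scale
        lo, hi = self.target_range
        z = (x - self.center) / self.scale  # in [0, 1] on the training range
        return np.clip(lo + (hi - lo) * z, lo, hi)


def fit_zscore(train_values: np.ndarray) -> Normalizer:
    """Z-score statistics per time point over training samples; zero-sd guard."""
    mean = train_values.mean(axis=0)
    sd = train_values.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return Normalizer(kind="zscore", center=mean, scale=sd)


def fit_minmax(train_values: np.ndarray, target_range=(-1.0, 1.0)) -> Normalizer:
    """Min-max statistics per time point; degenerate columns map to the midpoint."""
    lo = train_values.min(axis=0)
    hi = train_values.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    span = np.where(degenerate, 1.0, span)
    # degenerate columns: (x - lo)/1 = 0 -> map to midpoint by shifting center
    lo = np.where(degenerate, lo - 0.5, lo)
    return Normalizer(kind="minmax", center=lo, scale=span, target_range=target_range)


def zscore_normalize(series: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Impute-free z-scoring of a complete cohort using training rows only."""
    norm = fit_zscore(series[train_idx])
    return norm.transform(series)


def minmax_normalize(
    series: np.ndarray, train_idx: np.ndarray, target_range=(-1.0, 1.0)
) -> np.ndarray:
    """Min-max rescaling to target_range using training rows; out-of-range clipped."""
    norm = fit_minmax(series[train_idx], target_range)
    return norm.transform(series)


def prepare(
    cohort: Cohort,
    fold_count: int = 3,
    seed: int = 0,
    normalization: str = "zscore",
    balance_training: bool = True,
) -> tuple[np.ndarray, SplitCohort]:
    """Impute, partition, and normalize a cohort.

    Returns the normalized complete series matrix and the split.  The
    executable order is imputation -> split -> normalization so that
    normalization statistics depend only on training rows.
    """
    complete = locf_impute(cohort.series)
    imputed = Cohort(
        spec=cohort.spec,
        series=complete,
        labels=cohort.labels,
        observed_mask=np.ones_like(complete, dtype=bool),
        overlap=cohort.overlap,
    )
    split = partition(
        imputed, fold_count=fold_count, seed=seed, balance_training=balance_training
    )
    if normalization == "zscore":
        values = zscore_normalize(complete, split.train_idx)
    elif normalization == "minmax":
        values = minmax_normalize(complete, split.train_idx)
    else:
        raise ValueError(f"unknown normalization '{normalization}'")
    return values, split


def write_split(split: SplitCohort, path) -> None:
    Path(path).write_text(split.to_json())
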