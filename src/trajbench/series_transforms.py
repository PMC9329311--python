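"""Feature-engineering front-ends for the classifier zoo.

Two transforms are provided:

* **Time-series-forest (TSF) interval statistics** — the series is covered
  by randomly positioned contiguous intervals; each interval contributes its
  mean, sample standard deviation, and ordinary-least-squares slope.  The
  intervals are drawn once per cohort (on the training data) and reused for
  every sample, giving a fixed 3-channel feature layout ordered by interval
  start so that 1-D convolutions see spatially coherent features.
* **Gramian angular (summation) field (GAF)** — a series rescaled to
  [-1, 1] is encoded as angles phi_t = arccos(x_t); the image
  G[i, j] = cos(phi_i + phi_j) preserves temporal structure along the
  diagonal (G[i, i] = 2 x_i^2 - 1), turning the series into an input for
  2-D convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Interval:
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class TSFConfig:
    n_intervals: int = 64
    min_length: int = 3
    seed: int = 0


def sample_intervals(T: int, config: TSFConfig) -> list[Interval]:
    """Draw the cohort's shared interval set: random starts and lengths.

    Starts are uniform over positions that admit ``min_length``; lengths are
    uniform on [min_length, T - start].  The list is sorted by (start,
    length) so the downstream feature layout is deterministic.
    """
    if config.min_length > T:
        raise ValueError(f"min_length {config.min_length} exceeds series length {T}")
    if config.min_length < 2:
        raise ValueError("min_length must be at least 2")
    rng = np.random.default_rng(config.seed)
    intervals = []
    for _ in range(config.n_intervals):
        start = int(rng.integers(0, T - config.min_length + 1))
        length = int(rng.integers(config.min_length, T - start + 1))
        intervals.append(Interval(start, length))
    return sorted(intervals, key=lambda iv: (iv.start, iv.length))


def tsf_transform(series: np.ndarray, intervals: list[Interval]) -> np.ndarray:
    """Interval statistics: rows x (3 channels: mean, sd, slope) x n_intervals.

    For one series returns shape (n_intervals, 3); for a matrix of series
    (n_samples, T) returns (n_samples, n_intervals, 3).  Standard deviation
    uses the n-1 denominator; the slope is the OLS slope against the time
    index within the interval.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    if np.isnan(x).any():
        raise ValueError("TSF features require complete series")
    n = x.shape[0]
    feats = np.empty((n, len(intervals), 3))
    for k, iv in enumerate(intervals):
        seg = x[:, iv.start : iv.stop]
        t = np.arange(iv.length, dtype=float)
        tc = t - t.mean()
        denom = (tc**2).sum()
        feats[:, k, 0] = seg.mean(axis=1)
        feats[:, k, 1] = seg.std(axis=1, ddof=1)
        feats[:, k, 2] = (seg * tc).sum(axis=1) / denom
    return feats[0] if np.asarray(series).ndim == 1 else feats


def gaf_transform(series: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Gramian angular summation field of series rescaled to [-1, 1].

    G[i, j] = cos(arccos(x_i) + arccos(x_j)) = x_i x_j - sqrt(1-x_i^2) sqrt(1-x_j^2).
    For one series returns (T, T); for a matrix returns (n_samples, T, T).
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    if np.nanmax(np.abs(x)) > 1 + tol:
        raise ValueError("GAF input must be rescaled to [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    comp = np.sqrt(1.0 - x**2)
    G = x[:, :, None] * x[:, None, :] - comp[:, :, None] * comp[:, None, :]
    return G[0] if np.asarray(series).ndim == 1 else G


def gaf_reconstruct(diagonal: np.ndarray, sign_mask: np.ndarray) -> np.ndarray:
    """Recover the rescaled series from a GAF diagonal and a stored sign mask."""
    mag = np.sqrt((np.asarray(diagonal) + 1.0) / 2.0)
    return np.where(np.asarray(sign_mask) >= 0, mag, -mag)
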