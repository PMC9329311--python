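"""Two-class longitudinal cohort simulation.

A cohort is a pair of classes of trajectories derived from a single prepared
reference curve.  Class differences are planted in one of two ways:

* **magnitude** — each trajectory is the reference plus a single additive
  offset drawn per individual; class 0 offsets ~ Normal(0, sigma), class 1
  offsets ~ Normal(delta, sigma).  delta is the effect size (difference of
  class means), sigma the dispersion that generates distributional overlap.
* **shape** — the reference is first summarized by a least-squares fit on a
  ten-column orthonormal polynomial basis; the single most shape-influential
  coefficient (found by a permutation/MSE screen) is re-drawn per individual
  from class-specific normal distributions on that coefficient's own scale,
  and the trajectory rebuilt from the basis.

On top of the planted signal, cohorts can be degraded with fixed-rate
missingness, beta-distributed visit irregularity, and class imbalance, the
data-quality axes along which classifier robustness is benchmarked.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from trajbench.reference_profiles import (
    MAX_LENGTH,
    MeasurementKind,
    ReferenceTrajectory,
)

# Benchmark condition grids.
EFFECT_SIZES = (0.25, 0.75, 1.25, 1.75, 2.25, 2.75)
DISPERSIONS = (0.25, 0.60, 0.95, 1.30, 1.65, 2.00)
MISSING_RATES = (0.0, 0.10, 0.25, 0.50)
IMBALANCE_RATIOS = (1.0, 0.75, 0.5, 0.25)
MAX_PER_CLASS = 2000


class Variation(str, Enum):
    MAGNITUDE = "magnitude"
    SHAPE = "shape"


class Irregularity(str, Enum):
    NONE = "none"
    MODERATE = "moderate"
    HIGH = "high"


#: Scaled-beta parameters (a, b, lo, hi) for per-individual dropped-visit
#: counts: moderate has support [0, 3] with mean 1, high has support [2, 5]
#: with mean 4.
IRREGULARITY_BETA = {
    Irregularity.MODERATE: (2.0, 4.0, 0.0, 3.0),
    Irregularity.HIGH: (4.0, 2.0, 2.0, 5.0),
}


@dataclass
class CohortSpec:
    """Declarative description of one simulated two-class cohort."""

    variation: Variation = Variation.MAGNITUDE
    effect_size: float = 1.75
    dispersion: float = 0.60
    missing_rate: float = 0.0
    irregularity: Irregularity = Irregularity.NONE
    imbalance_ratio: float = 1.0
    n_per_class: int = 2000
    length: int = 16
    measurement_kind: MeasurementKind = MeasurementKind.BMI
    seed: int = 0

    def __post_init__(self) -> None:
        self.variation = Variation(self.variation)
        self.irregularity = Irregularity(self.irregularity)
        self.measurement_kind = MeasurementKind(self.measurement_kind)
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 1 <= self.n_per_class <= MAX_PER_CLASS:
            raise ValueError(f"n_per_class must be in [1, {MAX_PER_CLASS}]")
        if not 1 <= self.length <= MAX_LENGTH:
            raise ValueError(f"length must be in [1, {MAX_LENGTH}]")

    def to_json(self) -> str:
        d = asdict(self)
        d["variation"] = self.variation.value
        d["irregularity"] = self.irregularity.value
        d["measurement_kind"] = self.measurement_kind.value
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        return cls(**json.loads(text))


@dataclass
class Cohort:
    """One simulated dataset: per-sample series, labels, observation masks."""

    spec: CohortSpec
    series: np.ndarray  # n_samples x T, NaN where missing
    labels: np.ndarray  # binary, class 0 = reference-like, class 1 = shifted
    observed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    overlap: float | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.observed_mask is None:
            self.observed_mask = ~np.isnan(self.series)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary")
        if not self.observed_mask.any(axis=1).all():
            raise ValueError("every sample must have at least one observed point")

    @property
    def n_samples(self) -> int:
        return self.series.shape[0]

    @property
    def length(self) -> int:
        return self.series.shape[1]

    def copy(self) -> "Cohort":
        return Cohort(
            spec=self.spec,
            series=self.series.copy(),
            labels=self.labels.copy(),
            observed_mask=self.observed_mask.copy(),
            overlap=self.overlap,
        )


@dataclass
class PolyFit:
    """Least-squares fit of a reference on a ten-column orthonormal polynomial basis."""

    coefficients: np.ndarray  # length 10
    basis: np.ndarray  # T x 10, mutually orthonormal columns
    intercept: float
    residual_mse: float

    def reconstruct(self, coefficients: np.ndarray | None = None) -> np.ndarray:
        c = self.coefficients if coefficients is None else np.asarray(coefficients)
        return self.intercept + self.basis @ c


def orthonormal_poly_basis(T: int, degree: int = 10) -> np.ndarray:
    """Orthonormal polynomial contrasts of degree 1..degree on the grid 0..T-1.

    Built by QR-decomposing the Vandermonde matrix of the centered time grid
    and dropping the constant column; columns have unit Euclidean norm and
    are mutually orthogonal (and orthogonal to the constant).  Signs are
    fixed so each column's trailing element is positive, making the basis
    deterministic.
    """
    if T < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} time points for a degree-{degree} basis; "
            f"got {T} (use a longer reference or a lower degree)"
        )
    t = np.arange(T, dtype=float)
    t = t - t.mean()
    V = np.vander(t, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    B = Q[:, 1:]
    signs = np.sign(B[-1, :])
    signs[signs == 0] = 1.0
    return B * signs


def fit_poly10(reference: ReferenceTrajectory, degree: int = 10) -> PolyFit:
    """Fit a polynomial regression with ten coefficients on an orthonormal basis."""
    if not reference.is_complete:
        raise ValueError("reference must be prepared (complete) before fitting")
    y = reference.values
    B = orthonormal_poly_basis(len(y), degree)
    intercept = float(y.mean())
    coefficients = B.T @ (y - intercept)
    fitted = intercept + B @ coefficients
    residual_mse = float(np.mean((y - fitted) ** 2))
    return PolyFit(
        coefficients=coefficients,
        basis=B,
        intercept=intercept,
        residual_mse=residual_mse,
    )


def influential_coefficient(
    fit: PolyFit,
    n_perm: int = 1000,
    seed: int = 0,
    return_table: bool = False,
):
    """Find the coefficient whose perturbation most changes the fitted curve.

    Each coefficient j is re-drawn ``n_perm`` times from Normal(c_j,
    |c_j| + 1e-6) (a relative perturbation so influence scales with
    coefficient magnitude), the curve rebuilt, and the MSE against the
    original fitted curve recorded.  The same standard-normal draws are
    shared across coefficients (common random numbers), so equal
    perturbation scales give exactly tied mean MSEs; ties break toward the
    lowest index.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    c = fit.coefficients
    k = len(c)
    z = rng.normal(size=n_perm)
    mean_mse = np.empty(k)
    for j in range(k):
        draws = c[j] + z * (abs(c[j]) + 1e-6)
        # only column j changes, so the curve delta is (draw - c_j) * basis_j
        delta = (draws[:, None] - c[j]) * fit.basis[:, j][None, :]
        mean_mse[j] = np.mean(delta**2, axis=1).mean()
    # ties (within float tolerance) break toward the lowest index
    index = int(np.flatnonzero(mean_mse >= mean_mse.max() * (1 - 1e-9))[0]) + 1
    if return_table:
        return index, mean_mse
    return index


def _check_magnitude_spec(spec: CohortSpec) -> None:
    if spec.variation is not Variation.MAGNITUDE:
        raise ValueError("spec.variation must be 'magnitude'")


def simulate_magnitude_cohort(reference: ReferenceTrajectory, spec: CohortSpec) -> Cohort:
    """Simulate a magnitude cohort: per-individual additive offsets.

    Class 0 offsets ~ Normal(0, sigma); class 1 offsets ~ Normal(delta,
    sigma).  A single offset per trajectory preserves the reference shape.
    """
    _check_magnitude_spec(spec)
    if not reference.is_complete:
        raise ValueError("reference must be prepared before simulation")
    ref = reference.values[: spec.length]
    if len(ref) < spec.length:
        raise ValueError("reference shorter than requested cohort length")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    offsets0 = rng.normal(0.0, spec.dispersion, size=n)
    offsets1 = rng.normal(spec.effect_size, spec.dispersion, size=n)
    series = np.concatenate(
        [ref[None, :] + offsets0[:, None], ref[None, :] + offsets1[:, None]]
    )
    labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    cohort = Cohort(spec=spec, series=series, labels=labels)
    cohort.overlap = class_overlap(cohort)
    return cohort


def simulate_shape_cohort(
    reference: ReferenceTrajectory,
    fit: PolyFit,
    influential_index: int,
    spec: CohortSpec,
) -> Cohort:
    """Simulate a shape cohort by modulating the influential basis coefficient.

    The coefficient j* is re-drawn per individual as c_j* + e with
    e ~ Normal(0, sigma*s) for class 0 and Normal(delta*s, sigma*s) for
    class 1, where the scale s = |c_j*| (or the RMS of all coefficients when
    c_j* is zero) puts the shared effect/dispersion grids on the
    coefficient's own scale.
    """
    if spec.variation is not Variation.SHAPE:
        raise ValueError("spec.variation must be 'shape'")
    k = len(fit.coefficients)
    if not 1 <= influential_index <= k:
        raise ValueError(f"influential_index must be in 1..{k}")
    j = influential_index - 1
    s = abs(fit.coefficients[j])
    if s == 0.0:
        s = float(np.sqrt(np.mean(fit.coefficients**2)))
        if s == 0.0:
            s = 1.0
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    e0 = rng.normal(0.0, spec.dispersion * s, size=n)
    e1 = rng.normal(spec.effect_size * s, spec.dispersion * s, size=n)
    base = fit.reconstruct()[: spec.length]
    col = fit.basis[: spec.length, j]
    series = np.concatenate(
        [base[None, :] + e0[:, None] * col[None, :],
         base[None, :] + e1[:, None] * col[None, :]]
    )
    labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    cohort = Cohort(spec=spec, series=series, labels=labels)
    cohort.overlap = class_overlap(cohort)
    return cohort


def class_overlap(cohort: Cohort) -> float:
    """Proportion of trajectories sharing values with the opposite class at all times.

    A trajectory "overlaps" when, at every time point, its value lies within
    the [min, max] envelope of the opposite class at that time point.
    Computed on complete (pre-missingness) series.
    """
    if np.isnan(cohort.series).any():
        raise ValueError("class overlap is defined on complete cohorts")
    mask1 = cohort.labels == 1
    x0, x1 = cohort.series[~mask1], cohort.series[mask1]
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both classes must be non-empty")
    inside0 = ((x0 >= x1.min(axis=0)) & (x0 <= x1.max(axis=0))).all(axis=1)
    inside1 = ((x1 >= x0.min(axis=0)) & (x1 <= x0.max(axis=0))).all(axis=1)
    return float((inside0.sum() + inside1.sum()) / cohort.n_samples)


def inject_missingness(
    cohort: Cohort, m: float, seed: int = 0, allow_any_rate: bool = False
) -> Cohort:
    """Drop exactly round(m*T) uniformly chosen points per trajectory."""
    if not allow_any_rate and not any(np.isclose(m, g) for g in MISSING_RATES):
        raise ValueError(
            f"missing rate {m} not in the benchmark grid {MISSING_RATES}; "
            "pass allow_any_rate=True to override"
        )
    if not 0 <= m < 1:
        raise ValueError("missing rate must be in [0, 1)")
    if m == 0:
        return cohort.copy()
    out = cohort.copy()
    T = out.length
    k = int(round(m * T))
    k = min(k, T - 1)  # never drop every point
    rng = np.random.default_rng(seed)
    for i in range(out.n_samples):
        drop = rng.choice(T, size=k, replace=False)
        out.series[i, drop] = np.nan
        out.observed_mask[i, drop] = False
    return out


def sample_irregularity_counts(
    level: Irregularity, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-individual dropped-visit counts from the level's scaled beta law."""
    a, b, lo, hi = IRREGULARITY_BETA[Irregularity(level)]
    return np.round(lo + (hi - lo) * rng.beta(a, b, size=n)).astype(int)


def inject_irregularity(cohort: Cohort, level: Irregularity | str, seed: int = 0) -> Cohort:
    """Drop a beta-distributed number of additional points per individual.

    Moderate irregularity drops 0-3 visits (mean 1), high drops 2-5 visits
    (mean 4); points are chosen uniformly among the still-observed ones,
    always leaving at least one observation.
    """
    level = Irregularity(level)
    if level is Irregularity.NONE:
        return cohort.copy()
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    counts = sample_irregularity_counts(level, out.n_samples, rng)
    for i, k in enumerate(counts):
        observed = np.flatnonzero(out.observed_mask[i])
        k = min(k, len(observed) - 1)
        if k <= 0:
            continue
        drop = rng.choice(observed, size=k, replace=False)
        out.series[i, drop] = np.nan
        out.observed_mask[i, drop] = False
    return out


def apply_imbalance(cohort: Cohort, r: float, seed: int = 0) -> Cohort:
    """Down-sample class 1 without replacement to round(r * n_class0)."""
    if not any(np.isclose(r, g) for g in IMBALANCE_RATIOS):
        raise ValueError(f"imbalance ratio {r} not in the benchmark grid {IMBALANCE_RATIOS}")
    if np.isclose(r, 1.0):
        return cohort.copy()
    idx0 = np.flatnonzero(cohort.labels == 0)
    idx1 = np.flatnonzero(cohort.labels == 1)
    target = int(round(r * len(idx0)))
    if target < 2:
        raise ValueError("imbalance would leave fewer than 2 minority samples")
    rng = np.random.default_rng(seed)
    keep1 = np.sort(rng.choice(idx1, size=target, replace=False))
    keep = np.concatenate([idx0, keep1])
    return Cohort(
        spec=cohort.spec,
        series=cohort.series[keep],
        labels=cohort.labels[keep],
        observed_mask=cohort.observed_mask[keep],
        overlap=cohort.overlap,
    )


def degrade(cohort: Cohort, spec: CohortSpec | None = None) -> Cohort:
    """Apply the spec's missingness, irregularity and imbalance in order."""
    spec = spec or cohort.spec
    out = inject_missingness(cohort, spec.missing_rate, seed=spec.seed + 1)
    out = inject_irregularity(out, spec.irregularity, seed=spec.seed + 2)
    out = apply_imbalance(out, spec.imbalance_ratio, seed=spec.seed + 3)
    return out


def simulate(reference: ReferenceTrajectory, spec: CohortSpec) -> Cohort:
    """Simulate a cohort end-to-end: planted signal plus data degradation."""
    if spec.variation is Variation.MAGNITUDE:
        clean = simulate_magnitude_cohort(reference, spec)
    else:
        fit = fit_poly10(reference)
        j = influential_coefficient(fit, seed=spec.seed)
        clean = simulate_shape_cohort(reference, fit, j, spec)
    return degrade(clean, spec)


def enumerate_grid(
    variations: Sequence[Variation | str] = (Variation.MAGNITUDE, Variation.SHAPE),
    effect_sizes: Sequence[float] = EFFECT_SIZES,
    dispersions: Sequence[float] = DISPERSIONS,
    missing_rates: Sequence[float] = MISSING_RATES,
    irregularities: Sequence[Irregularity | str] = tuple(Irregularity),
    imbalance_ratios: Sequence[float] = IMBALANCE_RATIOS,
    measurement_kinds: Sequence[MeasurementKind | str] = (MeasurementKind.BMI,),
    n_per_class: int = 2000,
    length: int = 16,
    base_seed: int = 0,
) -> list[CohortSpec]:
    """Cartesian product of the requested condition axes, deterministically ordered.

    Each spec gets a unique derived seed so cohorts are independently
    reproducible.
    """
    axes = [
        variations,
        measurement_kinds,
        effect_sizes,
        dispersions,
        missing_rates,
        irregularities,
        imbalance_ratios,
    ]
    for ax in axes:
        if len(ax) == 0:
            raise ValueError("every grid axis must be non-empty")
    specs = []
    for i, (var, kind, d, s, m, irr, r) in enumerate(itertools.product(*axes)):
        specs.append(
            CohortSpec(
                variation=var,
                effect_size=d,
                dispersion=s,
                missing_rate=m,
                irregularity=irr,
                imbalance_ratio=r,
                n_per_class=n_per_class,
                length=length,
                measurement_kind=kind,
                seed=(base_seed * 1_000_003 + i * 7919 + 1) % (2**31),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# serialization

def cohort_to_frame(cohort: Cohort, cohort_id: str = "cohort") -> pd.DataFrame:
    cols = {f"t{t}": cohort.series[:, t] for t in range(cohort.length)}
    return pd.DataFrame(
        {
            "cohort_id": cohort_id,
            "sample_id": np.arange(cohort.n_samples),
            "class": cohort.labels,
            **cols,
        }
    )


def write_cohort(cohort: Cohort, path, cohort_id: str = "cohort") -> None:
    """Write the cohort table (CSV or parquet by extension) plus a JSON spec sidecar."""
    path = Path(path)
    df = cohort_to_frame(cohort, cohort_id)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".spec.json")
    sidecar.write_text(cohort.spec.to_json())


def read_cohort(path) -> Cohort:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".spec.json")
    spec = CohortSpec.from_json(sidecar.read_text())
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    tcols.sort(key=lambda c: int(c[1:]))
    series = df[tcols].to_numpy(dtype=float)
    cohort = Cohort(spec=spec, series=series, labels=df["class"].to_numpy(dtype=int))
    return cohort
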