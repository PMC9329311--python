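"""Observation-window pipeline for pediatric growth records.

The pipeline turns per-visit height/weight records into yearly BMI
trajectories and trains a classifier to predict a later-childhood outcome
(a type-2-diabetes-like label) from the BMI values inside an "observation
window" of ages, with the outcome assessed in the fixed 13-18 prediction
window.  Steps: quality control (record-level plausibility bounds plus
patient-level modified z-scores against reference growth tables),
individual-level local-polynomial smoothing of height and weight, BMI
computation (US units: 703 * lb / in^2), harmonization to one BMI per
integer year with linear interpolation of interior gaps, and per-window
dataset construction restricted to patients covering the window.  Windows
never extend past age 12 (the average onset age); window AUCs are compared
against the best window with DeLong's test and FDR correction.

Real growth-record data are rarely shareable, so a synthetic generator
produces visit streams with growth-curve-shaped height/weight, irregular
visit spacing, a planted elevated-BMI-slope signal in cases, and a
configurable sprinkling of implausible records to exercise QC.  The
packaged age-sex reference centile tables are synthetic stand-ins, not
national reference data; real tables are pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trajbench.benchmark_stats import DelongResult, delong_test, fdr_adjust

MIN_AGE, MAX_OBS_AGE, MAX_AGE = 2, 12, 18

# record-level plausibility bounds (exclusive of the bound itself per the
# "<=" / ">=" convention below)
HEIGHT_BOUNDS_IN = (25.0, 100.0)
WEIGHT_BOUNDS_LB = (5.0, 1000.0)

# patient-level modified z-score exclusion ranges
WEIGHT_Z_RANGE = (-5.0, 8.0)
HEIGHT_Z_RANGE = (-5.0, 4.0)
BMI_Z_RANGE = (-4.0, 8.0)


def bmi_from_us_units(weight_lb, height_in):
    """BMI from pounds and inches: 703 * weight / height^2."""
    height_in = np.asarray(height_in, dtype=float)
    if np.any(height_in <= 0):
        raise ValueError("height must be positive")
    return 703.0 * np.asarray(weight_lb, dtype=float) / height_in**2


def synthetic_growth_reference() -> pd.DataFrame:
    """Synthetic age-sex reference growth table (median and spread).

    Columns: sex, age, height_med, height_sd, weight_med, weight_sd,
    bmi_med, bmi_sd.  Values follow smooth, plausibly scaled pediatric
    growth curves; they stand in for national reference tables so the
    pipeline runs self-contained, and are labelled synthetic for that
    reason.
    """
    rows = []
    for sex in ("F", "M"):
        bump = 0.0 if sex == "F" else 1.0
        for age in range(MIN_AGE, MAX_AGE + 1):
            a = float(age)
            height = 30.0 + 4.2 * a - 0.09 * a**2 + bump  # inches, decelerating
            bmi = 16.2 - 0.45 * a + 0.055 * a**2  # dips then rises (adiposity rebound)
            weight = bmi * height**2 / 703.0
            rows.append(
                {
                    "sex": sex,
                    "age": age,
                    "height_med": height,
                    "height_sd": 1.6 + 0.12 * a,
                    "weight_med": weight,
                    "weight_sd": 0.12 * weight,
                    "bmi_med": bmi,
                    "bmi_sd": 0.11 * bmi,
                }
            )
    return pd.DataFrame(rows)


def generate_synthetic_ehr(
    n_patients: int,
    outcome_rate: float = 0.066,
    implausible_fraction: float = 0.004,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic pediatric visit stream with planted outcome signal.

    Returns ``(visits, patients)``: visits have columns patient_id, sex,
    age_at_visit, height_in, weight_lb; patients have patient_id, sex,
    label, onset_age (NaN for controls).  Cases (prevalence
    ``outcome_rate``) carry an elevated BMI trajectory slope; a small
    fraction of records are implausible or extreme to exercise QC.
    """
    if n_patients < 100:
        raise ValueError("need at least 100 patients")
    rng = np.random.default_rng(seed)
    ref = synthetic_growth_reference()
    visit_rows = []
    patient_rows = []
    for pid in range(n_patients):
        sex = "F" if rng.random() < 0.5 else "M"
        label = int(rng.random() < outcome_rate)
        onset_age = float(rng.uniform(12.5, 17.5)) if label else np.nan
        first = rng.uniform(2.0, 5.0)
        last = rng.uniform(13.0, 18.0)
        ages = [first]
        while ages[-1] < last:
            ages.append(ages[-1] + rng.uniform(0.6, 1.6))
        ages = np.array(ages[:-1]) if len(ages) > 1 else np.array(ages)
        ages = ages[ages <= MAX_AGE]
        if len(ages) < 3:
            ages = np.array([first, first + 1.0, first + 2.0])
        sub = ref[ref.sex == sex].set_index("age")
        h_med = np.interp(ages, sub.index, sub.height_med)
        b_med = np.interp(ages, sub.index, sub.bmi_med)
        b_sd = np.interp(ages, sub.index, sub.bmi_sd)
        height_factor = rng.normal(0.0, 0.8)
        heights = h_med + height_factor * np.interp(ages, sub.index, sub.height_sd)
        heights = heights + rng.normal(0.0, 0.35, size=len(ages))
        bmi_level = rng.normal(0.2 if label else 0.0, 0.8)
        bmi_slope = rng.normal(0.22 if label else 0.0, 0.05)  # planted case signal, z/year
        z = bmi_level + bmi_slope * (ages - MIN_AGE) + rng.normal(0, 0.15, len(ages))
        bmis = b_med + z * b_sd
        weights = bmis * heights**2 / 703.0
        for a, h, w in zip(ages, heights, weights):
            if rng.random() < implausible_fraction:
                # corrupt the record: unit-error-like implausible value
                if rng.random() < 0.5:
                    h = rng.choice([20.0, 110.0])
                else:
                    w = rng.choice([3.0, 1100.0])
            visit_rows.append(
                {
                    "patient_id": pid,
                    "sex": sex,
                    "age_at_visit": float(a),
                    "height_in": float(h),
                    "weight_lb": float(w),
                }
            )
        patient_rows.append(
            {"patient_id": pid, "sex": sex, "label": label, "onset_age": onset_age}
        )
    return pd.DataFrame(visit_rows), pd.DataFrame(patient_rows)


def qc_filter(
    visits: pd.DataFrame, reference: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply plausibility bounds and modified-z exclusions.

    Record-level: height <= 25 or >= 100 inches, weight <= 5 or >= 1000 lb
    removes the record.  Patient-level: any record with weight z outside
    (-5, 8], height z outside (-5, 4], or BMI z outside (-4, 8] (modified
    z against the age-sex reference table) removes the patient.  Returns
    ``(clean_visits, exclusion_log)``; the log records the rule fired.
    """
    if reference is None:
        reference = synthetic_growth_reference()
    if reference.empty:
        raise ValueError("a reference growth table is required for z-score QC")
    df = visits.copy()
    log = []

    h_lo, h_hi = HEIGHT_BOUNDS_IN
    w_lo, w_hi = WEIGHT_BOUNDS_LB
    bad_h = (df.height_in <= h_lo) | (df.height_in >= h_hi)
    bad_w = (df.weight_lb <= w_lo) | (df.weight_lb >= w_hi)
    for idx in df.index[bad_h]:
        log.append({"patient_id": df.at[idx, "patient_id"], "rule": "implausible_height",
                    "level": "record"})
    for idx in df.index[bad_w & ~bad_h]:
        log.append({"patient_id": df.at[idx, "patient_id"], "rule": "implausible_weight",
                    "level": "record"})
    df = df[~(bad_h | bad_w)].copy()

    # modified z against the reference table
    age_round = df.age_at_visit.round().clip(MIN_AGE, MAX_AGE).astype(int)
    key = pd.MultiIndex.from_arrays([df.sex, age_round])
    ref_idx = reference.set_index(["sex", "age"])
    ref_rows = ref_idx.loc[key]
    hz = (df.height_in.to_numpy() - ref_rows.height_med.to_numpy()) / ref_rows.height_sd.to_numpy()
    wz = (df.weight_lb.to_numpy() - ref_rows.weight_med.to_numpy()) / ref_rows.weight_sd.to_numpy()
    bmi = bmi_from_us_units(df.weight_lb.to_numpy(), df.height_in.to_numpy())
    bz = (bmi - ref_rows.bmi_med.to_numpy()) / ref_rows.bmi_sd.to_numpy()
    flag = pd.Series(index=df.index, dtype=object)
    flag[(wz < WEIGHT_Z_RANGE[0]) | (wz > WEIGHT_Z_RANGE[1])] = "weight_z"
    flag[(hz < HEIGHT_Z_RANGE[0]) | (hz > HEIGHT_Z_RANGE[1])] = "height_z"
    flag[(bz <= BMI_Z_RANGE[0]) | (bz > BMI_Z_RANGE[1])] = "bmi_z"
    bad_patients = df.loc[flag.notna(), "patient_id"].unique()
    for pid in bad_patients:
        rule = flag[df.patient_id == pid].dropna().iloc[0]
        log.append({"patient_id": pid, "rule": str(rule), "level": "patient"})
    df = df[~df.patient_id.isin(bad_patients)].copy()
    return df.reset_index(drop=True), pd.DataFrame(log, columns=["patient_id", "rule", "level"])


def _local_linear_smooth(
    x: np.ndarray, y: np.ndarray, bandwidth: float
) -> tuple[np.ndarray, float]:
    """Gaussian-kernel local linear fit; returns fitted values and trace(S)."""
    n = len(x)
    fitted = np.empty(n)
    trace = 0.0
    for i in range(n):
        w = np.exp(-0.5 * ((x - x[i]) / bandwidth) ** 2)
        X = np.stack([np.ones(n), x - x[i]], axis=1)
        XtW = X.T * w
        A = XtW @ X
        A[0, 0] += 1e-10
        A[1, 1] += 1e-10
        coef_row = np.linalg.solve(A, XtW)[0]  # row of the smoother matrix
        fitted[i] = coef_row @ y
        trace += coef_row[i]
    return fitted, trace


def smooth_series(
    ages: np.ndarray, values: np.ndarray, bandwidths: np.ndarray | None = None
) -> tuple[np.ndarray, bool]:
    """Local polynomial (degree-1) smoothing with GCV-selected bandwidth.

    Returns ``(smoothed_values, passthrough_flag)``; series with fewer than
    4 points pass through unchanged with the flag set.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        return values.copy(), True
    if bandwidths is None:
        span = ages.max() - ages.min()
        bandwidths = np.array([0.5, 0.75, 1.0, 1.5, 2.0]) * max(span / 8.0, 0.25)
    best = (np.inf, values)
    for bw in bandwidths:
        fitted, tr = _local_linear_smooth(ages, values, bw)
        denom = n - tr
        if denom <= 1e-8:
            continue
        gcv = n * np.sum((values - fitted) ** 2) / denom**2
        if gcv < best[0]:
            best = (gcv, fitted)
    return best[1], False


def bmi_series(visits: pd.DataFrame, smooth: bool = True) -> pd.DataFrame:
    """Per-patient (age, BMI) series from QC-passed visits.

    Height and weight are smoothed separately at the individual level
    before BMI computation (series shorter than 4 points pass through).
    """
    out = []
    for pid, grp in visits.groupby("patient_id", sort=True):
        grp = grp.sort_values("age_at_visit")
        ages = grp.age_at_visit.to_numpy()
        h = grp.height_in.to_numpy()
        w = grp.weight_lb.to_numpy()
        if smooth:
            h, _ = smooth_series(ages, h)
            w, _ = smooth_series(ages, w)
        bmi = bmi_from_us_units(w, h)
        for a, b in zip(ages, bmi):
            out.append({"patient_id": pid, "age": a, "bmi": b})
    return pd.DataFrame(out)


def yearly_harmonize(ages: np.ndarray, values: np.ndarray) -> pd.Series:
    """One value per integer-year segment [a, a+1): segment mean, interior gaps
    linearly interpolated, no extrapolation outside the observed span."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) == 0:
        raise ValueError("empty series")
    years = np.floor(ages).astype(int)
    seg = pd.Series(values).groupby(years).mean()
    full = pd.Series(
        index=range(seg.index.min(), seg.index.max() + 1), dtype=float
    )
    full.loc[seg.index] = seg.to_numpy()
    return full.interpolate(method="linear", limit_area="inside")


def harmonize_cohort(
    bmi: pd.DataFrame, patients: pd.DataFrame, truncate_at_onset: bool = True
) -> pd.DataFrame:
    """Patients x integer-years BMI table.

    Case records at/after onset age are dropped before harmonization;
    uncovered years are NaN.
    """
    onset = patients.set_index("patient_id").onset_age
    rows = {}
    for pid, grp in bmi.groupby("patient_id", sort=True):
        grp = grp.sort_values("age")
        if truncate_at_onset and pid in onset.index and np.isfinite(onset.loc[pid]):
            grp = grp[grp.age < onset.loc[pid]]
        if grp.empty:
            continue
        rows[pid] = yearly_harmonize(grp.age.to_numpy(), grp.bmi.to_numpy())
    table = pd.DataFrame(rows).T
    table = table.reindex(columns=range(MIN_AGE, MAX_AGE + 1))
    table.index.name = "patient_id"
    return table


@dataclass
class WindowedDataset:
    """Complete yearly BMI features over one observation window."""

    window: tuple[int, int]
    patient_ids: np.ndarray
    X: np.ndarray  # patients x window length
    y: np.ndarray

    @property
    def length(self) -> int:
        return self.window[1] - self.window[0] + 1


def default_windows(min_length: int = 2) -> list[tuple[int, int]]:
    """All integer windows [a, b] with 2 <= a < b <= 12 and length >= min_length."""
    return [
        (a, b)
        for a in range(MIN_AGE, MAX_OBS_AGE)
        for b in range(a + 1, MAX_OBS_AGE + 1)
        if b - a + 1 >= min_length
    ]


def build_windows(
    yearly: pd.DataFrame,
    patients: pd.DataFrame,
    windows: list[tuple[int, int]] | None = None,
) -> list[WindowedDataset]:
    """One dataset per window, keeping only patients with full coverage."""
    if windows is None:
        windows = default_windows()
    labels = patients.set_index("patient_id").label
    datasets = []
    for a, b in windows:
        if not (MIN_AGE <= a < b <= MAX_OBS_AGE):
            raise ValueError(f"window [{a}, {b}] outside ages {MIN_AGE}..{MAX_OBS_AGE}")
        block = yearly.loc[:, a:b]
        covered = block.dropna(axis=0, how="any")
        ids = covered.index.to_numpy()
        datasets.append(
            WindowedDataset(
                window=(a, b),
                patient_ids=ids,
                X=covered.to_numpy(dtype=float),
                y=labels.loc[ids].to_numpy(dtype=int),
            )
        )
    return datasets


def compare_windows(
    window_scores: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]],
    reference_window: tuple[int, int],
) -> pd.DataFrame:
    """DeLong each window's test AUC against the reference (best) window.

    ``window_scores`` maps window -> (patient_ids, scores, labels) on that
    window's test set; each comparison uses the intersection of test
    patients so the paired test is valid.  P values are BH-adjusted.
    """
    ref_ids, ref_scores, ref_labels = window_scores[reference_window]
    ref_pos = {pid: i for i, pid in enumerate(ref_ids)}
    rows = []
    for window, (ids, scores, labels) in window_scores.items():
        if window == reference_window:
            continue
        common = [pid for pid in ids if pid in ref_pos]
        if not common:
            raise ValueError(f"window {window} shares no test patients with the reference")
        pos = {pid: i for i, pid in enumerate(ids)}
        a_idx = np.array([pos[p] for p in common])
        r_idx = np.array([ref_pos[p] for p in common])
        res: DelongResult = delong_test(
            scores[a_idx], ref_scores[r_idx], labels[a_idx]
        )
        rows.append(
            {
                "window": f"{window[0]}-{window[1]}",
                "auc": res.auc_a,
                "reference_auc": res.auc_b,
                "z": res.z,
                "p": res.p_value,
                "n_common": len(common),
            }
        )
    columns = ["window", "auc", "reference_auc", "z", "p", "n_common"]
    df = pd.DataFrame(rows, columns=columns)
    df["fdr_p"] = fdr_adjust(df["p"].to_numpy()) if len(df) else np.nan
    return df
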