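"""Growth-record QC, harmonization, and observation-window construction."""

import numpy as np
import pandas as pd
import pytest

from trajbench import ehr_pipeline as ep


@pytest.fixture(scope="module")
def small_cohort():
    return ep.generate_synthetic_ehr(400, seed=3)


class TestBmi:
    def test_us_unit_formula(self):
        assert np.isclose(ep.bmi_from_us_units(100.0, 50.0), 28.12)

    def test_doubling_height_quarters_bmi(self):
        b1 = ep.bmi_from_us_units(80.0, 40.0)
        b2 = ep.bmi_from_us_units(80.0, 80.0)
        assert np.isclose(b2, b1 / 4)

    def test_zero_weight(self):
        assert ep.bmi_from_us_units(0.0, 50.0) == 0.0

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            ep.bmi_from_us_units(100.0, 0.0)


def make_visits(rows):
    return pd.DataFrame(rows, columns=["patient_id", "sex", "age_at_visit", "height_in", "weight_lb"])


class TestQcFilter:
    def test_implausible_height_record_excluded(self):
        visits = make_visits([(1, "F", 5.0, 24.0, 40.0), (1, "F", 6.0, 45.0, 45.0)])
        clean, log = ep.qc_filter(visits)
        assert len(clean) == 1
        assert (log.rule == "implausible_height").any()

    def test_implausible_weight_record_excluded(self):
        visits = make_visits([(1, "M", 8.0, 50.0, 1000.0)])
        clean, log = ep.qc_filter(visits)
        assert clean.empty
        assert (log.rule == "implausible_weight").any()

    def test_extreme_z_excludes_patient(self):
        ref = ep.synthetic_growth_reference()
        row = ref[(ref.sex == "F") & (ref.age == 8)].iloc[0]
        tall = row.height_med + 10 * row.height_sd  # way past the +4 bound
        visits = make_visits(
            [(1, "F", 8.0, tall, row.weight_med), (1, "F", 9.0, 55.0, 60.0)]
        )
        clean, log = ep.qc_filter(visits)
        assert clean.empty  # patient-level exclusion removes all records
        assert (log.level == "patient").any()

    def test_clean_cohort_untouched(self):
        ref = ep.synthetic_growth_reference()
        rows = []
        for pid in range(3):
            for age in (4, 6, 8):
                r = ref[(ref.sex == "M") & (ref.age == age)].iloc[0]
                rows.append((pid, "M", float(age), r.height_med, r.weight_med))
        visits = make_visits(rows)
        clean, log = ep.qc_filter(visits)
        assert len(clean) == len(visits) and log.empty

    def test_monotone_adding_passing_record(self, small_cohort):
        visits, _ = small_cohort
        clean, log = ep.qc_filter(visits)
        ref = ep.synthetic_growth_reference()
        r = ref[(ref.sex == "F") & (ref.age == 7)].iloc[0]
        extra = make_visits([(10**6, "F", 7.0, r.height_med, r.weight_med)])
        clean2, log2 = ep.qc_filter(pd.concat([visits, extra], ignore_index=True))
        assert len(log2) == len(log)
        assert len(clean2) == len(clean) + 1


class TestSmoothing:
    def test_noiseless_line_reproduced(self):
        ages = np.linspace(2, 10, 9)
        values = 3.0 + 2.0 * ages
        smoothed, flag = ep.smooth_series(ages, values)
        assert not flag
        np.testing.assert_allclose(smoothed, values, atol=1e-6)

    def test_noise_variance_reduced(self, rng):
        ages = np.linspace(2, 12, 20)
        trend = 30 + 2.5 * ages
        noisy = trend + rng.normal(0, 1.5, 20)
        smoothed, _ = ep.smooth_series(ages, noisy)
        assert np.var(smoothed - trend) < np.var(noisy - trend)

    def test_short_series_passthrough(self):
        ages = np.array([2.0, 3.0, 4.0])
        values = np.array([16.0, 15.5, 15.8])
        out, flag = ep.smooth_series(ages, values)
        assert flag
        np.testing.assert_array_equal(out, values)


class TestYearlyHarmonize:
    def test_segment_mean(self):
        out = ep.yearly_harmonize(np.array([4.2, 4.8]), np.array([16.0, 18.0]))
        assert np.isclose(out.loc[4], 17.0)

    def test_interior_interpolation(self):
        out = ep.yearly_harmonize(np.array([4.5, 6.5]), np.array([16.0, 20.0]))
        assert np.isclose(out.loc[5], 18.0)

    def test_no_extrapolation(self):
        out = ep.yearly_harmonize(np.array([4.2, 6.1]), np.array([16.0, 17.0]))
        assert 3 not in out.index

    def test_conserves_segment_means(self, rng):
        ages = np.sort(rng.uniform(3, 10, 25))
        values = rng.uniform(14, 30, 25)
        out = ep.yearly_harmonize(ages, values)
        years = np.floor(ages).astype(int)
        for yr in np.unique(years):
            assert np.isclose(out.loc[yr], values[years == yr].mean())


class TestWindows:
    def _yearly(self):
        # patient 0 covers 3..12, patient 1 covers 6..10
        data = {
            0: {yr: 16.0 + yr for yr in range(3, 13)},
            1: {yr: 15.0 + yr for yr in range(6, 11)},
        }
        table = pd.DataFrame(data).T.reindex(columns=range(2, 19))
        table.index.name = "patient_id"
        return table

    def _patients(self):
        return pd.DataFrame(
            {"patient_id": [0, 1], "sex": ["F", "M"], "label": [1, 0],
             "onset_age": [np.nan, np.nan]}
        )

    def test_coverage_rule(self):
        ds = ep.build_windows(self._yearly(), self._patients(), [(3, 12)])[0]
        assert list(ds.patient_ids) == [0]  # patient 1 lacks coverage

    def test_window_feature_length(self):
        ds = ep.build_windows(self._yearly(), self._patients(), [(3, 12)])[0]
        assert ds.X.shape[1] == 10 and ds.length == 10

    def test_out_of_bounds_window_rejected(self):
        with pytest.raises(ValueError, match="outside ages"):
            ep.build_windows(self._yearly(), self._patients(), [(3, 13)])

    def test_default_enumeration_count(self):
        # all [a, b] with 2 <= a < b <= 12 -> C(11, 2) = 55 windows
        assert len(ep.default_windows()) == 55
        assert len(ep.default_windows(min_length=3)) == 45


class TestSyntheticEhr:
    def test_prevalence_within_binomial_error(self):
        _, patients = ep.generate_synthetic_ehr(10_000, seed=1)
        rate = patients.label.mean()
        se = np.sqrt(0.066 * (1 - 0.066) / 10_000)
        assert abs(rate - 0.066) < 4 * se

    def test_deterministic(self):
        v1, p1 = ep.generate_synthetic_ehr(200, seed=9)
        v2, p2 = ep.generate_synthetic_ehr(200, seed=9)
        pd.testing.assert_frame_equal(v1, v2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_age_bounds(self, small_cohort):
        visits, _ = small_cohort
        assert visits.age_at_visit.between(2, 18).all()

    def test_case_truncation_at_onset(self, small_cohort):
        visits, patients = small_cohort
        clean, _ = ep.qc_filter(visits)
        bmi = ep.bmi_series(clean, smooth=False)
        yearly = ep.harmonize_cohort(bmi, patients)
        case = patients[patients.label == 1].iloc[0]
        onset_year = int(np.floor(case.onset_age))
        row = yearly.loc[case.patient_id]
        assert row.loc[onset_year + 1 :].isna().all()


class TestCompareWindows:
    def test_reference_not_in_rows_and_bh_property(self, rng):
        labels = np.array([0, 1] * 30)
        ids = np.arange(60)
        scores = {
            (3, 12): (ids, labels + rng.normal(0, 1.0, 60), labels),
            (2, 4): (ids, labels + rng.normal(0, 3.0, 60), labels),
            (5, 10): (ids, labels + rng.normal(0, 2.0, 60), labels),
        }
        table = ep.compare_windows(scores, (3, 12))
        assert len(table) == 2
        assert "3-12" not in table.window.tolist()
        assert (table.fdr_p >= table.p - 1e-12).all()

    def test_disjoint_test_sets_rejected(self, rng):
        labels = np.array([0, 1] * 10)
        scores = {
            (3, 12): (np.arange(20), labels + rng.normal(0, 1, 20), labels),
            (2, 4): (np.arange(100, 120), labels + rng.normal(0, 1, 20), labels),
        }
        with pytest.raises(ValueError, match="shares no test patients"):
            ep.compare_windows(scores, (3, 12))
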