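"""Cohort simulation: polynomial fits, signal planting, degradation axes."""

import numpy as np
import pytest

from trajbench import cohort_simulator as cs
from trajbench import reference_profiles as rp


def make_spec(**kw):
    defaults = dict(
        variation="magnitude", effect_size=1.75, dispersion=0.6,
        n_per_class=200, length=16, measurement_kind="bmi", seed=7,
    )
    defaults.update(kw)
    return cs.CohortSpec(**defaults)


class TestPolyFit:
    def test_basis_orthonormal(self):
        B = cs.orthonormal_poly_basis(16)
        np.testing.assert_allclose(B.T @ B, np.eye(10), atol=1e-10)
        # orthogonal to the constant
        np.testing.assert_allclose(B.sum(axis=0), 0, atol=1e-9)

    def test_low_degree_polynomial_nests(self, rng):
        t = np.arange(16, dtype=float)
        y = 2.0 + 0.3 * t - 0.02 * t**2
        ref = rp.ReferenceTrajectory("bmi", y / np.median(y) + 1)  # positive series
        fit = cs.fit_poly10(ref)
        assert fit.residual_mse < 1e-18
        np.testing.assert_allclose(fit.coefficients[2:], 0, atol=1e-9)

    def test_mse_beats_constant_fit(self, prepared_reference):
        fit = cs.fit_poly10(prepared_reference)
        assert fit.residual_mse <= np.var(prepared_reference.values) + 1e-12

    def test_projection_of_basis_column(self):
        B = cs.orthonormal_poly_basis(16)
        y = 5.0 * B[:, 2] + 3.0  # third orthonormal column plus intercept
        ref = rp.ReferenceTrajectory("bmi", y, observed_mask=np.ones(16, bool))
        fit = cs.fit_poly10(ref)
        assert np.isclose(fit.coefficients[2], 5.0, atol=1e-9)
        others = np.delete(fit.coefficients, 2)
        np.testing.assert_allclose(others, 0, atol=1e-9)

    def test_too_short_reference_rejected(self):
        ref = rp.ReferenceTrajectory("bmi", np.linspace(1, 2, 10))
        with pytest.raises(ValueError, match="longer reference"):
            cs.fit_poly10(ref)


class TestInfluentialCoefficient:
    def test_dominant_coefficient_found(self):
        B = cs.orthonormal_poly_basis(16)
        c = np.full(10, 0.01)
        c[6] = 10.0  # coefficient 7 dominates
        fit = cs.PolyFit(coefficients=c, basis=B, intercept=1.0, residual_mse=0.0)
        assert cs.influential_coefficient(fit, seed=0) == 7

    def test_all_zero_ties_break_low(self):
        B = cs.orthonormal_poly_basis(16)
        fit = cs.PolyFit(coefficients=np.zeros(10), basis=B, intercept=1.0, residual_mse=0.0)
        assert cs.influential_coefficient(fit, seed=0) == 1

    def test_deterministic_given_seed(self, poly_fit):
        i1, t1 = cs.influential_coefficient(poly_fit, seed=3, return_table=True)
        i2, t2 = cs.influential_coefficient(poly_fit, seed=3, return_table=True)
        assert i1 == i2
        np.testing.assert_array_equal(t1, t2)

    def test_mean_mse_scales_with_coefficient_magnitude(self):
        """Brute-force check: expected MSE per coefficient is ~(|c_j|+eps)^2/T."""
        B = cs.orthonormal_poly_basis(16)
        c = np.array([0.1, 2.0, 0.5, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        fit = cs.PolyFit(coefficients=c, basis=B, intercept=0.0, residual_mse=0.0)
        _, table = cs.influential_coefficient(fit, n_perm=20000, seed=1, return_table=True)
        expected = (np.abs(c) + 1e-6) ** 2 / 16
        np.testing.assert_allclose(table[:3], expected[:3], rtol=0.05)

    def test_invalid_n_perm(self, poly_fit):
        with pytest.raises(ValueError):
            cs.influential_coefficient(poly_fit, n_perm=0)


class TestMagnitudeCohort:
    def test_degenerate_dispersion_limit(self, prepared_reference):
        spec = make_spec(dispersion=1e-9, n_per_class=20)
        cohort = cs.simulate_magnitude_cohort(prepared_reference, spec)
        class1 = cohort.series[cohort.labels == 1]
        expected = prepared_reference.values + spec.effect_size
        np.testing.assert_allclose(class1, np.tile(expected, (20, 1)), atol=1e-6)

    def test_effect_size_recovered_at_full_cohort_size(self, prepared_reference):
        spec = make_spec(effect_size=2.75, dispersion=0.25, n_per_class=2000, seed=11)
        cohort = cs.simulate_magnitude_cohort(prepared_reference, spec)
        offsets = cohort.series - prepared_reference.values
        diff = offsets[cohort.labels == 1].mean() - offsets[cohort.labels == 0].mean()
        bound = 3 * 0.25 * np.sqrt(2 / 2000)
        assert abs(diff - 2.75) < bound

    def test_grid_axes(self):
        assert len(cs.EFFECT_SIZES) == 6 and len(cs.DISPERSIONS) == 6
        np.testing.assert_allclose(np.diff(cs.EFFECT_SIZES), 0.5)
        np.testing.assert_allclose(np.diff(cs.DISPERSIONS), 0.35)

    def test_reproducible(self, prepared_reference):
        a = cs.simulate_magnitude_cohort(prepared_reference, make_spec())
        b = cs.simulate_magnitude_cohort(prepared_reference, make_spec())
        np.testing.assert_array_equal(a.series, b.series)


class TestShapeCohort:
    def test_degenerate_dispersion_collapses_classes(self, prepared_reference, poly_fit):
        j = cs.influential_coefficient(poly_fit, seed=0)
        spec = make_spec(variation="shape", dispersion=1e-12, n_per_class=15)
        cohort = cs.simulate_shape_cohort(prepared_reference, poly_fit, j, spec)
        c0 = cohort.series[cohort.labels == 0]
        c1 = cohort.series[cohort.labels == 1]
        np.testing.assert_allclose(c0, np.tile(poly_fit.reconstruct(), (15, 1)), atol=1e-8)
        np.testing.assert_allclose(c1, np.tile(c1[0], (15, 1)), atol=1e-8)

    def test_series_mean_unchanged_by_modulation(self, prepared_reference, poly_fit):
        """Basis columns are orthogonal to the intercept, so modulating a
        coefficient leaves per-series means untouched."""
        j = cs.influential_coefficient(poly_fit, seed=0)
        spec = make_spec(variation="shape", effect_size=2.0, dispersion=1.0, n_per_class=50)
        cohort = cs.simulate_shape_cohort(prepared_reference, poly_fit, j, spec)
        base_mean = poly_fit.reconstruct().mean()
        np.testing.assert_allclose(cohort.series.mean(axis=1), base_mean, atol=1e-6)

    def test_class_coefficient_separation(self, prepared_reference, poly_fit):
        j = cs.influential_coefficient(poly_fit, seed=0)
        s = abs(poly_fit.coefficients[j - 1])
        spec = make_spec(variation="shape", effect_size=1.5, dispersion=0.3,
                         n_per_class=2000, seed=5)
        cohort = cs.simulate_shape_cohort(prepared_reference, poly_fit, j, spec)
        col = poly_fit.basis[:, j - 1]
        coefs = (cohort.series - poly_fit.reconstruct()) @ col  # recover e_i
        diff = coefs[cohort.labels == 1].mean() - coefs[cohort.labels == 0].mean()
        assert abs(diff - 1.5 * s) < 3 * 0.3 * s * np.sqrt(2 / 2000)

    def test_bad_index_rejected(self, prepared_reference, poly_fit):
        with pytest.raises(ValueError):
            cs.simulate_shape_cohort(
                prepared_reference, poly_fit, 11, make_spec(variation="shape")
            )


class TestClassOverlap:
    def test_disjoint_supports(self):
        series = np.vstack([np.zeros((10, 4)), np.full((10, 4), 10.0)])
        labels = np.array([0] * 10 + [1] * 10)
        cohort = cs.Cohort(spec=make_spec(), series=series, labels=labels)
        assert cs.class_overlap(cohort) == 0.0

    def test_identical_distributions_near_one(self, prepared_reference):
        spec = make_spec(effect_size=1e-12, dispersion=1.0, n_per_class=2000)
        cohort = cs.simulate_magnitude_cohort(prepared_reference, spec)
        assert cs.class_overlap(cohort) > 0.9

    def test_constructed_envelopes(self):
        """10 class-0 curves inside class 1's envelope; 1 of 10 class-1 curves
        inside class 0's envelope -> overlap 11/20."""
        T = 4
        class0 = np.vstack([np.full((1, T), v) for v in np.linspace(1, 2, 10)])
        # one class-1 curve inside [1, 2]; the rest outside, but spanning it
        outside = [0.5] + [20.0 + i for i in range(8)]
        class1 = np.vstack([np.full((1, T), 1.5)] + [np.full((1, T), v) for v in outside])
        cohort = cs.Cohort(
            spec=make_spec(),
            series=np.vstack([class0, class1]),
            labels=np.array([0] * 10 + [1] * 10),
        )
        assert np.isclose(cs.class_overlap(cohort), 11 / 20)

    def test_overlap_monotone_in_effect_size(self, prepared_reference):
        overlaps = []
        for delta in cs.EFFECT_SIZES:
            spec = make_spec(effect_size=delta, dispersion=0.6, n_per_class=2000, seed=3)
            overlaps.append(cs.simulate_magnitude_cohort(prepared_reference, spec).overlap)
        assert all(a >= b - 1e-12 for a, b in zip(overlaps[:-1], overlaps[1:]))


class TestMissingness:
    def test_zero_rate_identity(self, prepared_reference):
        cohort = cs.simulate_magnitude_cohort(prepared_reference, make_spec())
        out = cs.inject_missingness(cohort, 0.0)
        np.testing.assert_array_equal(out.series, cohort.series)

    @pytest.mark.parametrize("rate, expected", [(0.10, 2), (0.25, 4), (0.50, 8)])
    def test_exact_counts_at_length_16(self, prepared_reference, rate, expected):
        cohort = cs.simulate_magnitude_cohort(prepared_reference, make_spec(n_per_class=30))
        out = cs.inject_missingness(cohort, rate, seed=1)
        counts = np.isnan(out.series).sum(axis=1)
        assert (counts == expected).all()

    def test_off_grid_rate_rejected_unless_overridden(self, prepared_reference):
        cohort = cs.simulate_magnitude_cohort(prepared_reference, make_spec(n_per_class=20))
        with pytest.raises(ValueError, match="grid"):
            cs.inject_missingness(cohort, 0.3)
        out = cs.inject_missingness(cohort, 0.3, allow_any_rate=True)
        assert (np.isnan(out.series).sum(axis=1) == round(0.3 * 16)).all()


class TestIrregularity:
    def test_none_is_identity(self, prepared_reference):
        cohort = cs.simulate_magnitude_cohort(prepared_reference, make_spec())
        out = cs.inject_irregularity(cohort, "none")
        np.testing.assert_array_equal(out.series, cohort.series)

    @pytest.mark.parametrize(
        "level, mean_range, support",
        [("moderate", (0.9, 1.1), (0, 3)), ("high", (3.9, 4.1), (2, 5))],
    )
    def test_scaled_beta_draw_contracts(self, level, mean_range, support, rng):
        counts = cs.sample_irregularity_counts(cs.Irregularity(level), 10_000, rng)
        assert mean_range[0] <= counts.mean() <= mean_range[1]
        assert counts.min() >= support[0] and counts.max() <= support[1]

    def test_every_sample_keeps_an_observation(self, prepared_reference):
        spec = make_spec(n_per_class=50, length=5)
        cohort = cs.simulate_magnitude_cohort(prepared_reference, spec)
        out = cs.inject_irregularity(cohort, "high", seed=2)
        assert out.observed_mask.any(axis=1).all()


class TestImbalance:
    def test_unit_ratio_identity(self, prepared_reference):
        cohort = cs.simulate_magnitude_cohort(prepared_reference, make_spec())
        out = cs.apply_imbalance(cohort, 1.0)
        np.testing.assert_array_equal(out.labels, cohort.labels)

    def test_quarter_ratio_counts(self, prepared_reference):
        cohort = cs.simulate_magnitude_cohort(prepared_reference, make_spec(n_per_class=2000))
        out = cs.apply_imbalance(cohort, 0.25, seed=1)
        assert (out.labels == 0).sum() == 2000
        assert (out.labels == 1).sum() == 500

    def test_half_ratio_exact(self, prepared_reference):
        cohort = cs.simulate_magnitude_cohort(prepared_reference, make_spec(n_per_class=100))
        out = cs.apply_imbalance(cohort, 0.5, seed=1)
        assert (out.labels == 1).sum() / (out.labels == 0).sum() == 0.5


class TestGridEnumeration:
    def test_full_single_measurement_grid(self):
        specs = cs.enumerate_grid(variations=["magnitude"])
        assert len(specs) == 6 * 6 * 4 * 3 * 4  # 1728

    def test_single_point_grid(self):
        specs = cs.enumerate_grid(
            variations=["magnitude"], effect_sizes=[0.25], dispersions=[0.6],
            missing_rates=[0.0], irregularities=["none"], imbalance_ratios=[1.0],
        )
        assert len(specs) == 1

    def test_three_kinds_full_product(self):
        specs = cs.enumerate_grid(
            variations=["magnitude"], measurement_kinds=["bmi", "glucose", "sbp"]
        )
        assert len(specs) == 5184

    def test_unique_seeds_and_deterministic_order(self):
        a = cs.enumerate_grid(variations=["shape"])
        b = cs.enumerate_grid(variations=["shape"])
        assert [s.seed for s in a] == [s.seed for s in b]
        assert len({s.seed for s in a}) == len(a)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            cs.enumerate_grid(effect_sizes=[])


def test_cohort_round_trip_csv(tmp_path, prepared_reference):
    spec = make_spec(n_per_class=25, missing_rate=0.25)
    cohort = cs.simulate(prepared_reference, spec)
    path = tmp_path / "cohort.csv"
    cs.write_cohort(cohort, path)
    back = cs.read_cohort(path)
    np.testing.assert_array_equal(back.labels, cohort.labels)
    np.testing.assert_allclose(back.series, cohort.series)
    assert back.spec == cohort.spec
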