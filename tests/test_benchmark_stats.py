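"""AUC, rank-based model comparison, DeLong, and FDR machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trajbench import benchmark_stats as bs


def brute_force_auc(scores, labels):
    """Concordance probability by explicit pair counting (ties count half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert bs.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        assert bs.roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_all_ties(self):
        assert bs.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.choice(np.linspace(0, 1, 10), size=40)  # include ties
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert np.isclose(bs.roc_auc(scores, labels), brute_force_auc(scores, labels))

    def test_negation_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert np.isclose(
            bs.roc_auc(scores, labels) + bs.roc_auc(-scores, labels), 1.0
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bs.roc_auc([0.1, 0.2], [1, 1])


class TestThresholdMetrics:
    def test_perfect_classifier(self):
        m = bs.threshold_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m["f1"] == m["precision"] == m["recall"] == m["specificity"] == 1.0

    def test_hand_confusion_table(self):
        m = bs.threshold_metrics([1, 1, 0, 0], [1, 0, 1, 0])
        assert m["precision"] == m["recall"] == m["specificity"] == m["f1"] == 0.5

    def test_all_predicted_negative(self):
        m = bs.threshold_metrics([0.1, 0.2, 0.3, 0.4], [1, 0, 1, 0])
        assert m["recall"] == 0.0 and m["specificity"] == 1.0
        assert m["precision"] == 0.0 and m["precision_undefined"]


class TestFriedman:
    def test_identical_columns_null(self):
        tbl = pd.DataFrame({"a": [0.7, 0.8, 0.9], "b": [0.7, 0.8, 0.9], "c": [0.7, 0.8, 0.9]})
        res = bs.friedman_rank(tbl)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constructed_statistic_eight(self):
        """3 models x 4 conditions, strict ordering every row -> chi2_F = 8."""
        tbl = pd.DataFrame(
            {"best": [0.9, 0.91, 0.92, 0.93],
             "mid": [0.8, 0.81, 0.82, 0.83],
             "worst": [0.7, 0.71, 0.72, 0.73]}
        )
        res = bs.friedman_rank(tbl)
        assert np.isclose(res.statistic, 8.0)
        np.testing.assert_allclose(res.mean_ranks.to_numpy(), [1.0, 2.0, 3.0])

    def test_column_permutation_equivariance(self, rng):
        tbl = pd.DataFrame(rng.random((8, 4)), columns=list("abcd"))
        res = bs.friedman_rank(tbl)
        perm = tbl[["c", "a", "d", "b"]]
        res_p = bs.friedman_rank(perm)
        for col in "abcd":
            assert np.isclose(res.mean_ranks[col], res_p.mean_ranks[col])
        assert np.isclose(res.statistic, res_p.statistic)

    def test_missing_cells_rejected(self):
        tbl = pd.DataFrame({"a": [0.1, np.nan], "b": [0.2, 0.3]})
        with pytest.raises(ValueError):
            bs.friedman_rank(tbl)

    def test_mean_ranks_average_to_center(self, rng):
        tbl = pd.DataFrame(rng.random((10, 5)))
        res = bs.friedman_rank(tbl)
        k = 5
        assert np.isclose(res.mean_ranks.mean(), (k + 1) / 2)
        assert res.critical_difference > 0

    def test_null_p_value_uniform(self):
        """Under a column-exchangeable null the Friedman p-value is uniform."""
        ps = []
        for i in range(1000):
            tbl = pd.DataFrame(np.random.default_rng(i).random((60, 5)))
            ps.append(bs.friedman_rank(tbl).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestDelong:
    def test_identical_scores(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        res = bs.delong_test(scores, scores, labels)
        assert res.p_value == 1.0

    def test_swap_symmetry(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = labels + rng.normal(0, 1, 40)
        b = labels + rng.normal(0, 2, 40)
        r1 = bs.delong_test(a, b, labels)
        r2 = bs.delong_test(b, a, labels)
        assert np.isclose(r1.z, -r2.z)
        assert np.isclose(r1.p_value, r2.p_value)

    def test_agrees_with_paired_bootstrap(self):
        """DeLong p on a 40-sample fixture vs a 10,000-resample paired
        bootstrap of the AUC difference."""
        rng = np.random.default_rng(7)
        labels = np.array([0, 1] * 20)
        a = labels + rng.normal(0, 1.2, 40)
        b = labels + rng.normal(0, 1.8, 40)
        res = bs.delong_test(a, b, labels)
        diffs = []
        n = 40
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            if len(np.unique(labels[idx])) < 2:
                continue
            diffs.append(bs.roc_auc(a[idx], labels[idx]) - bs.roc_auc(b[idx], labels[idx]))
        diffs = np.array(diffs)
        observed = res.auc_a - res.auc_b
        # two-sided normal-approximation bootstrap p
        boot_p = 2 * sps.norm.sf(abs(observed) / diffs.std())
        assert abs(res.p_value - boot_p) < 0.1

    def test_type_one_error_calibrated(self):
        """Two noisy copies of the same signal: rejection rate ~ alpha."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 2000
        labels = np.array([0, 1] * 30)
        for _ in range(n_rep):
            base = labels + rng.normal(0, 1, 60)
            a = base + rng.normal(0, 0.5, 60)
            b = base + rng.normal(0, 0.5, 60)
            if bs.delong_test(a, b, labels).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) < 0.02

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(ValueError):
            bs.delong_test([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bs.fdr_adjust([0.03]), [0.03])

    def test_step_up_hand_case(self):
        np.testing.assert_allclose(
            bs.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_two_value_hand_case(self):
        np.testing.assert_allclose(bs.fdr_adjust([0.001, 0.9]), [0.002, 0.9])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(20)
        assert (bs.fdr_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bs.fdr_adjust([0.1, 1.2])


class TestOverfitDelta:
    def test_identical_train_test(self):
        rows = pd.DataFrame(
            {"arch": ["a", "a"], "train_auc": [0.8, 0.9], "test_auc": [0.8, 0.9]}
        )
        assert bs.overfit_delta(rows)["a"] == 0.0

    def test_hand_mean(self):
        rows = pd.DataFrame(
            {"arch": ["m", "m"], "train_auc": [0.9, 0.8], "test_auc": [0.85, 0.75]}
        )
        assert np.isclose(bs.overfit_delta(rows)["m"], 0.05)

    def test_order_invariance(self, rng):
        rows = pd.DataFrame(
            {"arch": ["x"] * 6, "train_auc": rng.random(6), "test_auc": rng.random(6)}
        )
        shuffled = rows.sample(frac=1, random_state=0)
        assert np.isclose(bs.overfit_delta(rows)["x"], bs.overfit_delta(shuffled)["x"])
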