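"""Metrics vs independent oracles; bootstrap and paired-test behavior."""

import numpy as np
import pytest

from drwnet.evaluation import (
    ConfusionCounts,
    binary_metrics,
    bootstrap_ci,
    multiclass_report,
    paired_t_test,
    roc_pr_curves,
    stagewise_sensitivity,
)


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        m = binary_metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        for value in (m.precision, m.sensitivity, m.accuracy, m.specificity, m.f1, m.dice):
            assert value == 1.0

    def test_hand_computed_counts(self):
        m = binary_metrics(ConfusionCounts(tp=9, fp=1, tn=87, fn=3))
        assert m.precision == pytest.approx(0.9)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.96)
        assert m.specificity == pytest.approx(87 / 88)
        assert m.f1 == pytest.approx(2 * 0.9 * 0.75 / (0.9 + 0.75))
        assert m.dice == pytest.approx(18 / (18 + 1 + 3))

    def test_f1_equals_dice_identity(self, rng):
        """2 Psn Ssv / (Psn + Ssv) == 2TP / (2TP + FP + FN) for any counts."""
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            m = binary_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert m.f1 == pytest.approx(m.dice, abs=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_zero_denominator_convention(self):
        m = binary_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.precision == 0.0 and m.sensitivity == 0.0


class TestMulticlassReport:
    def test_perfect_predictions(self, rng):
        y = rng.integers(0, 5, 100)
        rep = multiclass_report(y, y)
        assert rep["macro"].f1 == 1.0
        assert np.allclose(np.diag(rep["matrix_normalized"]), 1.0)

    def test_against_brute_force_tally(self, rng):
        """Independent counting oracle on 200 random labels."""
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        rep = multiclass_report(y_true, y_pred)
        brute = np.zeros((5, 5), dtype=int)
        for t, p in zip(y_true, y_pred):
            brute[t, p] += 1
        assert np.array_equal(rep["matrix"], brute)

    def test_against_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix, f1_score, precision_score, recall_score

        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        rep = multiclass_report(y_true, y_pred)
        assert np.array_equal(rep["matrix"], confusion_matrix(y_true, y_pred))
        assert rep["macro"].f1 == pytest.approx(f1_score(y_true, y_pred, average="macro"))
        assert rep["weighted"].f1 == pytest.approx(f1_score(y_true, y_pred, average="weighted"))
        assert rep["macro"].precision == pytest.approx(
            precision_score(y_true, y_pred, average="macro", zero_division=0)
        )
        assert rep["macro"].sensitivity == pytest.approx(
            recall_score(y_true, y_pred, average="macro", zero_division=0)
        )

    def test_weighted_equals_macro_for_balanced_support(self, rng):
        y_true = np.repeat(np.arange(5), 20)
        y_pred = rng.integers(0, 5, 100)
        rep = multiclass_report(y_true, y_pred)
        assert rep["macro"].f1 == pytest.approx(rep["weighted"].f1, abs=1e-12)

    def test_joint_permutation_invariance(self, rng):
        y_true = rng.integers(0, 5, 100)
        y_pred = rng.integers(0, 5, 100)
        perm = rng.permutation(100)
        a = multiclass_report(y_true, y_pred)
        b = multiclass_report(y_true[perm], y_pred[perm])
        assert np.array_equal(a["matrix"], b["matrix"])
        assert a["macro"].f1 == b["macro"].f1

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            multiclass_report([0, 7], [0, 1])


class TestCurves:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        scores = np.eye(5)[y] * 0.9 + 0.02
        out = roc_pr_curves(y, scores)
        for c in range(5):
            assert out["auc"][c] == pytest.approx(1.0)
            assert out["ap"][c] == pytest.approx(1.0)

    def test_constant_scores_chance_auc(self):
        y = np.array([0, 1, 0, 1, 2, 3, 4, 2, 3, 4])
        scores = np.full((10, 5), 0.2)
        out = roc_pr_curves(y, scores)
        for c in range(5):
            assert out["auc"][c] == pytest.approx(0.5)

    def test_auc_matches_exhaustive_threshold_oracle(self, rng):
        """Brute force: AUC = P(score_pos > score_neg) + 0.5 P(tie)."""
        y = rng.integers(0, 5, 20)
        scores = rng.uniform(0, 1, (20, 5))
        scores /= scores.sum(axis=1, keepdims=True)
        out = roc_pr_curves(y, scores)
        for c in range(5):
            pos = scores[y == c, c]
            neg = scores[y != c, c]
            if len(pos) == 0 or len(neg) == 0:
                assert out["auc"][c] is None
                continue
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert out["auc"][c] == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 5, 40)
        scores = rng.uniform(0, 1, (40, 5))
        out1 = roc_pr_curves(y, scores)
        out2 = roc_pr_curves(y, np.exp(3 * scores))
        for c in range(5):
            if out1["auc"][c] is not None:
                assert out1["auc"][c] == pytest.approx(out2["auc"][c], abs=1e-12)

    def test_absent_class_reported_missing(self):
        y = np.array([0, 0, 1, 1])
        scores = np.full((4, 5), 0.2)
        out = roc_pr_curves(y, scores)
        assert out["auc"][3] is None


class TestBootstrap:
    @staticmethod
    def _acc(a, b):
        return float((a == b).mean())

    def test_constant_metric_zero_width(self):
        y = np.zeros(20, dtype=int)
        mean, sd, lo, hi = bootstrap_ci(self._acc, y, y, iters=200, seed=0)
        assert mean == lo == hi == 1.0
        assert sd == 0.0

    def test_seeded_determinism(self, rng):
        y_true = rng.integers(0, 5, 50)
        y_pred = rng.integers(0, 5, 50)
        a = bootstrap_ci(self._acc, y_true, y_pred, iters=300, seed=7)
        b = bootstrap_ci(self._acc, y_true, y_pred, iters=300, seed=7)
        assert a == b

    def test_empirical_coverage_near_nominal(self):
        """Over 200 replications of a known-accuracy classifier, the 95%
        interval should cover the true accuracy about 95% of the time."""
        true_acc = 0.8
        n = 200
        master = np.random.default_rng(2024)
        covered = 0
        reps = 200
        for rep in range(reps):
            correct = master.uniform(size=n) < true_acc
            y_true = np.zeros(n, dtype=int)
            y_pred = np.where(correct, 0, 1)
            _, _, lo, hi = bootstrap_ci(
                self._acc, y_true, y_pred, iters=1000, seed=rep
            )
            covered += lo <= true_acc <= hi
        assert abs(covered / reps - 0.95) <= 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(self._acc, np.array([1]), np.array([1]))


class TestPairedT:
    def test_identical_scores(self):
        t, p = paired_t_test([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert t == 0.0 and p == 1.0

    def test_small_noise_large_shift_significant(self, rng):
        a = 0.9 + rng.normal(0, 1e-4, 5)
        b = 0.4 + rng.normal(0, 1e-4, 5)
        t, p = paired_t_test(a, b)
        assert p < 1e-6

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([2.0, 4.0, 6.0], [1.0, 3.0, 5.0])

    def test_matches_scipy(self, rng):
        from scipy import stats as sps

        a = rng.uniform(0.7, 0.9, 5)
        b = rng.uniform(0.7, 0.9, 5)
        t, p = paired_t_test(a, b)
        t2, p2 = sps.ttest_rel(a, b)
        assert t == pytest.approx(t2) and p == pytest.approx(p2)


class TestStagewise:
    def test_perfect_predictions_full_sensitivity(self, rng):
        y = rng.integers(0, 5, 50)
        scores = np.eye(5)[y]
        rows = stagewise_sensitivity(y, y, scores)
        for row in rows:
            if not row["missing"]:
                assert row["sensitivity"] == 1.0

    def test_absent_grade_flagged(self):
        y = np.array([0, 0, 1, 1])
        scores = np.full((4, 5), 0.2)
        rows = stagewise_sensitivity(y, y, scores)
        assert rows[4]["missing"] is True

    def test_agrees_with_binary_reduction(self, rng):
        from drwnet.evaluation import _ovr_counts

        y_true = rng.integers(0, 5, 100)
        y_pred = rng.integers(0, 5, 100)
        scores = rng.uniform(0, 1, (100, 5))
        rows = stagewise_sensitivity(y_true, y_pred, scores)
        for c in range(5):
            if rows[c]["missing"]:
                continue
            m = binary_metrics(_ovr_counts(y_true, y_pred, c))
            assert rows[c]["sensitivity"] == m.sensitivity
            assert rows[c]["precision"] == m.precision
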