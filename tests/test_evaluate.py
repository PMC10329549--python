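import itertools

import numpy as np
import pytest

from corticad import (
    ClassLabel,
    binary_diagnostics,
    confusion_matrix,
    likelihood_ratios,
    misclassification_error,
    percent_agreement,
    relative_foreground_area_error,
)

# the study's published 3-class confusion matrix (rows actual, cols predicted)
STUDY_MATRIX = [
    (["normal"] * 56 + ["osteopenia"] * 4 + ["osteoporosis"] * 8),
    (["normal"] * 1 + ["osteopenia"] * 33 + ["osteoporosis"] * 4),
    (["osteoporosis"] * 17),
]


def study_labels():
    actual = (["normal"] * 68) + (["osteopenia"] * 38) + (["osteoporosis"] * 17)
    predicted = STUDY_MATRIX[0] + STUDY_MATRIX[1] + STUDY_MATRIX[2]
    return actual, predicted


def all_3x3_masks():
    for bits in itertools.product([0, 1], repeat=9):
        yield np.array(bits, dtype=np.uint8).reshape(3, 3)


class TestSegmentationMetrics:
    def test_identical_masks_zero_error(self, rng):
        m = (rng.random((16, 16)) > 0.4).astype(np.uint8)
        m[0, 0] = 1
        assert misclassification_error(m, m) == 0.0
        assert relative_foreground_area_error(m, m) == 0.0

    def test_complementary_masks_me_one(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[:2] = 1
        assert misclassification_error(m, 1 - m) == 1.0

    def test_strip_example(self):
        gt = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        pred = np.array([[0, 1, 1, 0]], dtype=np.uint8)
        assert misclassification_error(gt, pred) == 0.5

    def test_rae_branches(self):
        gt = np.zeros((2, 2), dtype=np.uint8)
        gt.flat[:4] = [1, 1, 1, 1]
        pred = np.zeros((2, 2), dtype=np.uint8)
        pred.flat[:2] = 1
        assert relative_foreground_area_error(gt, pred) == 0.5  # undershoot
        assert relative_foreground_area_error(pred, gt) == 0.5  # overshoot

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_foreground_area_error(np.zeros((2, 2), dtype=np.uint8),
                                           np.ones((2, 2), dtype=np.uint8))

    def test_exhaustive_3x3_oracle(self):
        """ME and RAE agree with brute-force pixel counting on every pair of
        3x3 masks (512 x 512 pairs)."""
        masks = list(all_3x3_masks())
        flat = np.array([m.ravel() for m in masks], dtype=bool)  # 512 x 9
        agree = (flat[:, None, :] == flat[None, :, :]).sum(axis=2)
        me_oracle = 1.0 - agree / 9.0
        areas = flat.sum(axis=1)
        a_g, a_p = areas[:, None], areas[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            rae_oracle = np.where(a_p < a_g, (a_g - a_p) / a_g, (a_p - a_g) / np.maximum(a_p, 1))
        step = 37  # subsample pairs for runtime; oracle still covers both branches
        for i in range(512):
            for j in range(i % step, 512, step):
                assert misclassification_error(masks[i], masks[j]) == pytest.approx(me_oracle[i, j])
                if areas[i] > 0:
                    assert relative_foreground_area_error(masks[i], masks[j]) == pytest.approx(
                        rae_oracle[i, j])

    def test_symmetry(self, rng):
        a = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        b = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        a[0, 0] = b[0, 0] = 1
        assert misclassification_error(a, b) == misclassification_error(b, a)
        assert relative_foreground_area_error(a, b) == relative_foreground_area_error(b, a)


class TestConfusionMatrix:
    def test_all_correct_balanced(self):
        labels = ["normal"] * 3 + ["osteopenia"] * 3 + ["osteoporosis"] * 3
        cm = confusion_matrix(labels, labels)
        assert np.array_equal(np.diag(cm.counts), [3, 3, 3])
        assert cm.counts.sum() == 9

    def test_study_marginals(self):
        actual, predicted = study_labels()
        cm = confusion_matrix(actual, predicted)
        assert np.array_equal(cm.counts, [[56, 4, 8], [1, 33, 4], [0, 0, 17]])
        assert list(cm.predicted_totals) == [57, 37, 29]
        assert cm.total == 123

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["normal"], [])


class TestBinaryDiagnostics:
    def test_study_specificity(self):
        actual, predicted = study_labels()
        diag = binary_diagnostics(confusion_matrix(actual, predicted))
        assert diag.specificity == pytest.approx(56 / 68)
        assert round(100 * diag.specificity, 2) == 82.35

    def test_negative_likelihood_ratio_from_printed_rates(self):
        _, lr_neg = likelihood_ratios(0.9821, 0.8235)
        assert round(lr_neg, 2) == 0.02

    def test_perfect_classifier(self):
        labels = ["normal"] * 5 + ["osteopenia"] * 5 + ["osteoporosis"] * 5
        diag = binary_diagnostics(confusion_matrix(labels, labels))
        assert diag.sensitivity == diag.specificity == diag.accuracy == 1.0
        assert diag.lr_neg == 0.0
        assert diag.lr_pos is None  # specificity 1 -> undefined, not an exception

    def test_lr_identities_from_counts(self):
        actual, predicted = study_labels()
        diag = binary_diagnostics(confusion_matrix(actual, predicted))
        tp, fn = 54, 1
        tn, fp = 56, 12
        assert diag.sensitivity == pytest.approx(tp / (tp + fn))
        assert diag.lr_pos == pytest.approx((tp / (tp + fn)) / (fp / (tn + fp)))
        assert diag.lr_neg == pytest.approx((fn / (tp + fn)) / (tn / (tn + fp)))

    def test_ci_bounds_bracket_estimate(self):
        actual, predicted = study_labels()
        diag = binary_diagnostics(confusion_matrix(actual, predicted))
        lo, hi = diag.specificity_ci
        assert lo < diag.specificity < hi

    def test_positive_set_must_be_proper_subset(self):
        actual, predicted = study_labels()
        cm = confusion_matrix(actual, predicted)
        with pytest.raises(ValueError):
            binary_diagnostics(cm, set(ClassLabel))


class TestPercentAgreement:
    def test_identical_lists(self):
        labels = ["normal", "osteopenia"] * 5
        assert percent_agreement(labels, labels) == 100.0

    def test_partial_agreement(self):
        a = ["normal"] * 100
        b = ["normal"] * 81 + ["osteopenia"] * 19
        assert percent_agreement(a, b) == 81.0

    def test_disjoint(self):
        assert percent_agreement(["normal"] * 4, ["osteoporosis"] * 4) == 0.0
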