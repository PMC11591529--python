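import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrseg.metrics import (
    ConfusionMatrix,
    classification_metrics,
    confusion_from_masks,
    f1_from_precision_recall,
    macro_mean,
    segmentation_metrics,
)
from oracles import confusion_loops, one_vs_rest_counts


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, rng):
        m = rng.integers(0, 3, size=(10, 10))
        cm = confusion_from_masks(m, m, 3)
        assert cm.counts.sum() == 100
        assert (cm.counts == np.diag(np.diag(cm.counts))).all()

    def test_all_background_pred_vs_all_mr_truth(self):
        pred = np.zeros((5, 5), dtype=int)
        truth = np.ones((5, 5), dtype=int)
        cm = confusion_from_masks(pred, truth, 3)
        assert cm.counts[1, 0] == 25
        assert cm.counts.sum() == 25

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            pred = rng.integers(0, 3, size=(6, 6))
            truth = rng.integers(0, 3, size=(6, 6))
            cm = confusion_from_masks(pred, truth, 3)
            assert (cm.counts == confusion_loops(pred, truth, 3)).all()

    def test_shape_mismatch_and_bad_labels_error(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_from_masks(np.zeros((2, 2)), np.zeros((3, 3)), 3)
        with pytest.raises(ValueError, match="labels"):
            confusion_from_masks(np.full((2, 2), 5), np.zeros((2, 2)), 3)


class TestSegmentationMetrics:
    def test_hand_counts(self):
        # MR one-vs-rest: TP=8, FP=1, FN=1
        counts = np.array([[90, 1, 0], [1, 8, 0], [0, 0, 0]])
        report = segmentation_metrics(ConfusionMatrix(counts), report_classes=(1,))
        mr = report.per_class["MR"]
        assert mr["jaccard"] == pytest.approx(0.8)
        assert mr["precision"] == pytest.approx(8 / 9)
        assert mr["recall"] == pytest.approx(8 / 9)

    def test_perfect_prediction_scores_one(self, rng):
        m = rng.integers(0, 3, size=(12, 12))
        report = segmentation_metrics(confusion_from_masks(m, m, 3))
        for cls in report.per_class.values():
            assert all(v == pytest.approx(1.0) for v in cls.values())
        assert report.mpa == pytest.approx(1.0)

    def test_single_target_mpa_equals_recall(self, rng):
        # only one evaluated class present: MPA collapses to that class recall
        truth = (rng.random((10, 10)) < 0.3).astype(int)  # labels {0,1}
        pred = (rng.random((10, 10)) < 0.3).astype(int)
        cm = confusion_from_masks(pred, truth, 3)
        report = segmentation_metrics(cm, report_classes=(1,))
        assert report.mpa == pytest.approx(report.per_class["MR"]["recall"])

    def test_matches_brute_force_counts(self, rng):
        pred = rng.integers(0, 3, size=(10, 10))
        truth = rng.integers(0, 3, size=(10, 10))
        cm = confusion_from_masks(pred, truth, 3)
        report = segmentation_metrics(cm)
        for c, name in ((1, "MR"), (2, "LA")):
            tp, fp, fn, tn = one_vs_rest_counts(cm.counts, c)
            assert report.per_class[name]["jaccard"] == pytest.approx(
                tp / (tp + fp + fn)
            )
            assert report.per_class[name]["precision"] == pytest.approx(tp / (tp + fp))
            assert report.per_class[name]["recall"] == pytest.approx(tp / (tp + fn))

    def test_empty_class_reports_zero_with_flag(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 10  # background only
        report = segmentation_metrics(ConfusionMatrix(counts))
        assert report.per_class["MR"]["jaccard"] == 0.0
        assert report.zero_division_flags


class TestClassificationMetrics:
    def test_identity_matrix_scores_100(self):
        report = classification_metrics(ConfusionMatrix(np.eye(3, dtype=int) * 10))
        for cls in report.per_class.values():
            assert all(v == pytest.approx(1.0) for v in cls.values())

    def test_f1_is_harmonic_mean_of_reported_precision_recall(self):
        # mild row of the reference cohort: P=87.86, R=89.03 -> F1 88.44
        assert f1_from_precision_recall(87.86, 89.03) == pytest.approx(88.44, abs=0.01)

    def test_macro_precision_of_reported_per_class_values(self):
        assert macro_mean([87.86, 88.44, 89.26]) == pytest.approx(88.52, abs=0.01)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_f1_identity_and_oracle_on_random_case_matrices(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(3, 3))
        counts[0, 0] += 1
        cm = ConfusionMatrix(counts)
        report = classification_metrics(cm)
        for c, name in enumerate(("mild", "moderate", "severe")):
            tp, fp, fn, tn = one_vs_rest_counts(cm.counts, c)
            vals = report.per_class[name]
            if tp + fp:
                assert vals["precision"] == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert vals["recall"] == pytest.approx(tp / (tp + fn))
            assert vals["accuracy"] == pytest.approx(
                (tp + tn) / (tp + tn + fp + fn)
            )
            if 2 * tp + fp + fn:
                assert vals["f1"] == pytest.approx(2 * tp / (2 * tp + fn + fp))
            # Eq. identity: 2TP/(2TP+FP+FN) == harmonic mean of P and R
            assert vals["f1"] == pytest.approx(
                f1_from_precision_recall(vals["precision"], vals["recall"])
            )
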