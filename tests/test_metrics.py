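"""Metric suite: hand-counted examples, oracle equivalence, invariants.

The oracle is an independent per-pixel counting implementation that
never builds a confusion matrix, so agreement is a genuine cross-check
of the bincount-based implementation.
"""

from __future__ import annotations

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from cattleseg.exceptions import DataError, UndefinedMetricError
from cattleseg.metrics import (ConfusionMatrix, accumulate,
                               class_pixel_accuracy, compute_report, iou,
                               mean_pixel_accuracy, miou, pixel_accuracy)

#: rows = ground truth, columns = prediction
WORKED = ConfusionMatrix.from_counts([[4, 1, 0], [0, 3, 1], [1, 0, 2]])


# -- independent oracle ------------------------------------------------------

def oracle_metrics(truth: np.ndarray, pred: np.ndarray, nc: int) -> dict:
    """Brute-force per-pixel counting, no confusion matrix involved."""
    t = truth.ravel()
    p = pred.ravel()
    correct = int((t == p).sum())
    cpa, ious = [], []
    for c in range(nc):
        tp = int(((t == c) & (p == c)).sum())
        fp = int(((t != c) & (p == c)).sum())
        fn = int(((t == c) & (p != c)).sum())
        cpa.append(tp / (tp + fp) if tp + fp else np.nan)
        ious.append(tp / (tp + fp + fn) if tp + fp + fn else np.nan)
    return {"pa": correct / t.size, "cpa": cpa, "iou": ious,
            "mpa": np.nanmean(cpa), "miou": np.nanmean(ious)}


# -- worked example ----------------------------------------------------------

class TestWorkedExample:
    def test_pixel_accuracy(self):
        assert pixel_accuracy(WORKED) == pytest.approx(0.75)

    def test_class_pixel_accuracy_is_the_printed_precision_form(self):
        assert class_pixel_accuracy(WORKED, 0) == pytest.approx(0.8)
        assert class_pixel_accuracy(WORKED, 1) == pytest.approx(0.75)
        assert class_pixel_accuracy(WORKED, 2) == pytest.approx(2 / 3)

    def test_recall_mode_divides_by_row_sums(self):
        assert class_pixel_accuracy(WORKED, 0, mode="recall") == pytest.approx(4 / 5)
        assert class_pixel_accuracy(WORKED, 1, mode="recall") == pytest.approx(3 / 4)
        assert class_pixel_accuracy(WORKED, 2, mode="recall") == pytest.approx(2 / 3)

    def test_mean_pixel_accuracy(self):
        assert mean_pixel_accuracy(WORKED) == pytest.approx((0.8 + 0.75 + 2 / 3) / 3)

    def test_per_class_iou_and_mean(self):
        assert iou(WORKED, 0) == pytest.approx(4 / 6)
        assert iou(WORKED, 1) == pytest.approx(3 / 5)
        assert iou(WORKED, 2) == pytest.approx(2 / 4)
        assert miou(WORKED) == pytest.approx((4 / 6 + 3 / 5 + 0.5) / 3)


# -- accumulation ------------------------------------------------------------

class TestAccumulation:
    def test_identity_prediction_fills_the_diagonal(self):
        cm = ConfusionMatrix(3)
        mask = np.ones((10, 10), dtype=np.uint8)
        accumulate(cm, mask, mask)
        assert cm.counts[1, 1] == 100
        assert cm.total == 100

    def test_empty_masks_change_nothing(self):
        cm = ConfusionMatrix(3)
        accumulate(cm, np.zeros((0,)), np.zeros((0,)))
        assert cm.total == 0

    def test_hand_counted_triplet(self):
        cm = ConfusionMatrix(3)
        accumulate(cm, predicted_mask=np.array([0, 2, 2]),
                   truth_mask=np.array([0, 1, 2]))
        expected = np.zeros((3, 3), dtype=np.int64)
        expected[0, 0] = expected[1, 2] = expected[2, 2] = 1
        np.testing.assert_array_equal(cm.counts, expected)

    def test_shape_mismatch_and_out_of_range_labels_are_data_errors(self):
        cm = ConfusionMatrix(3)
        with pytest.raises(DataError, match="shape"):
            cm.add(np.zeros((2, 2)), np.zeros((3, 2)))
        with pytest.raises(DataError, match="truth"):
            cm.add(np.full((2, 2), 5), np.zeros((2, 2)))
        with pytest.raises(DataError, match="predicted"):
            cm.add(np.zeros((2, 2)), np.full((2, 2), 7))

    def test_batch_accumulation_is_additive(self):
        rng = np.random.default_rng(0)
        t1, p1 = rng.integers(0, 3, (2, 8, 8))
        t2, p2 = rng.integers(0, 3, (2, 8, 8))
        split = ConfusionMatrix(3).add(t1, p1).add(t2, p2)
        joined = ConfusionMatrix(3).add(np.concatenate([t1, t2]),
                                        np.concatenate([p1, p2]))
        np.testing.assert_array_equal(split.counts, joined.counts)


# -- degenerate cases --------------------------------------------------------

class TestDegenerateCases:
    def test_empty_matrix_has_no_pixel_accuracy(self):
        with pytest.raises(UndefinedMetricError):
            pixel_accuracy(ConfusionMatrix(3))

    def test_absent_class_is_nan_and_excluded_from_the_means(self):
        # class 2 never occurs in truth or prediction
        cm = ConfusionMatrix.from_counts([[5, 1, 0], [2, 4, 0], [0, 0, 0]])
        assert np.isnan(class_pixel_accuracy(cm, 2))
        assert np.isnan(iou(cm, 2))
        report = compute_report(cm)
        assert report.undefined_classes == ["beef"]
        assert report.mpa == pytest.approx((5 / 7 + 4 / 5) / 2)
        assert report.miou == pytest.approx((5 / 8 + 4 / 7) / 2)

    def test_all_classes_undefined_raises(self):
        cm = ConfusionMatrix(2)
        with pytest.raises(UndefinedMetricError):
            miou(cm)

    def test_perfect_and_fully_wrong_predictions(self):
        perfect = ConfusionMatrix.from_counts(np.diag([5, 6, 7]))
        assert pixel_accuracy(perfect) == 1.0
        assert miou(perfect) == 1.0
        assert mean_pixel_accuracy(perfect) == 1.0
        wrong = ConfusionMatrix.from_counts([[0, 3], [3, 0]])
        assert pixel_accuracy(wrong) == 0.0
        assert iou(wrong, 0) == 0.0

    def test_single_class_mpa_equals_cpa(self):
        cm = ConfusionMatrix.from_counts([[9]], class_names=["only"])
        assert mean_pixel_accuracy(cm) == class_pixel_accuracy(cm, 0) == 1.0

    def test_ignore_index_excludes_pixels(self):
        cm = ConfusionMatrix(2)
        cm.add(np.array([0, 1, 255]), np.array([0, 0, 1]), ignore_index=255)
        assert cm.total == 2


# -- properties --------------------------------------------------------------

mask_pair = st.integers(1, 4).flatmap(
    lambda nc: st.tuples(
        st.just(nc),
        hnp.arrays(np.int64, (12, 12), elements=st.integers(0, nc - 1)),
        hnp.arrays(np.int64, (12, 12), elements=st.integers(0, nc - 1))))


class TestProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(mask_pair)
    def test_every_metric_matches_the_counting_oracle(self, tpl):
        nc, truth, pred = tpl
        cm = ConfusionMatrix(nc).add(truth, pred)
        ref = oracle_metrics(truth, pred, nc)
        assert pixel_accuracy(cm) == pytest.approx(ref["pa"])
        for c in range(nc):
            got = class_pixel_accuracy(cm, c)
            assert (np.isnan(got) and np.isnan(ref["cpa"][c])) or \
                got == pytest.approx(ref["cpa"][c])
            got = iou(cm, c)
            assert (np.isnan(got) and np.isnan(ref["iou"][c])) or \
                got == pytest.approx(ref["iou"][c])
        assert mean_pixel_accuracy(cm) == pytest.approx(ref["mpa"])
        assert miou(cm) == pytest.approx(ref["miou"])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(mask_pair, st.randoms(use_true_random=False))
    def test_relabelling_both_masks_preserves_the_means(self, tpl, rnd):
        nc, truth, pred = tpl
        perm = np.array(rnd.sample(range(nc), nc))
        a = ConfusionMatrix(nc).add(truth, pred)
        b = ConfusionMatrix(nc).add(perm[truth], perm[pred])
        assert pixel_accuracy(a) == pytest.approx(pixel_accuracy(b))
        assert mean_pixel_accuracy(a) == pytest.approx(mean_pixel_accuracy(b))
        assert miou(a) == pytest.approx(miou(b))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(mask_pair)
    def test_iou_never_exceeds_cpa(self, tpl):
        nc, truth, pred = tpl
        cm = ConfusionMatrix(nc).add(truth, pred)
        for c in range(nc):
            i, p = iou(cm, c), class_pixel_accuracy(cm, c)
            if not (np.isnan(i) or np.isnan(p)):
                assert i <= p + 1e-12

    def test_agrees_with_sklearn_confusion_matrix(self):
        from sklearn.metrics import confusion_matrix as sk_cm
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 3, 500)
        pred = rng.integers(0, 3, 500)
        cm = ConfusionMatrix(3).add(truth, pred)
        np.testing.assert_array_equal(
            cm.counts, sk_cm(truth, pred, labels=[0, 1, 2]))


def test_report_serialization_uses_the_customary_columns(tmp_path):
    report = compute_report(WORKED)
    row = report.table_row()
    assert list(row) == ["PA", "MPA", "MIoU", "CPA(Cow)", "CPA(Beef)",
                         "IoU(Cow)", "IoU(Beef)"]
    path = tmp_path / "report.json"
    report.to_json(path)
    loaded = json.loads(path.read_text())
    assert loaded["PA"] == pytest.approx(0.75)
    assert loaded["MIoU"] == pytest.approx(0.58888, abs=1e-4)
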