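"""Matching protocol, confusion matrices, accuracy rendering, fixtures."""

import numpy as np
import pytest

from stumprot.detector import Detection
from stumprot.evaluation import (
    ConfusionMatrix,
    confusion_matrix,
    load_reference_tables,
    match_detections,
    per_class_accuracy,
    render_int_percent,
    reproduce_reference_tables,
    truncate_percent,
)
from stumprot.segquality import BoundingBox


def det(x0, y0, x1, y1, score):
    return Detection(bbox=BoundingBox(x0, y0, x1, y1), score=score)


class TestMatchDetections:
    def test_single_true_positive(self):
        res = match_detections([det(0, 0, 10, 10, 0.9)],
                               [BoundingBox(0, 2, 10, 12)])
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)
        assert res.precision == 1.0 and res.recall == 1.0

    def test_missed_label_is_fn(self):
        res = match_detections([], [BoundingBox(0, 0, 10, 10)])
        assert (res.tp, res.fp, res.fn) == (0, 0, 1)

    def test_two_detections_one_label_is_tp_plus_fp(self):
        dets = [det(0, 0, 10, 10, 0.9), det(1, 0, 11, 10, 0.8)]
        res = match_detections(dets, [BoundingBox(0, 0, 10, 10)])
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_below_threshold_is_fp(self):
        res = match_detections([det(0, 0, 10, 10, 0.9)],
                               [BoundingBox(30, 30, 40, 40)])
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_boundary_comparison_configurable(self):
        # sq exactly 0.5: half-overlapping equal-area boxes
        dets = [det(0, 5, 10, 15, 0.9)]
        labels = [BoundingBox(0, 0, 10, 10)]
        assert match_detections(dets, labels, comparison="ge").tp == 1
        assert match_detections(dets, labels, comparison="gt").tp == 0

    def test_unsorted_scores_rejected(self):
        with pytest.raises(ValueError):
            match_detections([det(0, 0, 5, 5, 0.5), det(0, 0, 5, 5, 0.9)], [])

    def test_conservation_laws(self, rng):
        """tp + fn = #labels and tp + fp = #detections, at random."""
        for _ in range(50):
            labels = [BoundingBox(int(x), int(y), int(x) + 12, int(y) + 12)
                      for x, y in rng.integers(0, 80, size=(rng.integers(0, 4), 2))]
            scores = np.sort(rng.random(rng.integers(0, 6)))[::-1]
            dets = [det(int(x), int(y), int(x) + 12, int(y) + 12, float(s))
                    for (x, y), s in zip(rng.integers(0, 80, size=(len(scores), 2)),
                                         scores)]
            res = match_detections(dets, labels)
            assert res.tp + res.fn == len(labels)
            assert res.tp + res.fp == len(dets)
            matched_labels = [m[1] for m in res.matches]
            assert len(matched_labels) == len(set(matched_labels))

    def test_reference_detection_counts_render(self):
        """TP=162, FP=9, FN=39 renders as 95% precision and 80% recall."""
        from stumprot.evaluation import DetectionEvalResult
        res = DetectionEvalResult(tp=162, fp=9, fn=39, matches=())
        assert res.precision == pytest.approx(162 / 171)
        assert res.recall == pytest.approx(162 / 201)
        assert render_int_percent(res.precision, "round") == "95%"
        assert render_int_percent(res.recall, "floor") == "80%"


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(["a", "b", "b"], ["a", "b", "b"], ["a", "b"])
        assert cm.counts.tolist() == [[1, 0], [0, 2]]

    def test_reference_two_class_counts_reconstructed(self):
        true = ["NO_ROT"] * 103 + ["ROT"] * 98
        pred = (["NO_ROT"] * 94 + ["ROT"] * 9) + (["NO_ROT"] * 9 + ["ROT"] * 89)
        cm = confusion_matrix(true, pred, ["NO_ROT", "ROT"])
        assert cm.counts.tolist() == [[94, 9], [9, 89]]
        accs = per_class_accuracy(cm)
        assert [a["rendered"] for a in accs] == ["91.2%", "90.8%"]

    def test_empty_input_is_zero_matrix(self):
        cm = confusion_matrix([], [], ["a", "b"])
        assert cm.counts.sum() == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["c"], ["a"], ["a", "b"])

    def test_zero_row_accuracy_undefined(self):
        cm = ConfusionMatrix(counts=np.array([[2, 0], [0, 0]]),
                             class_order=("a", "b"))
        with pytest.raises(ValueError):
            per_class_accuracy(cm)

    def test_identity_matrix_is_all_hundreds(self):
        cm = ConfusionMatrix(counts=np.eye(3, dtype=int), class_order=("a", "b", "c"))
        assert [a["rendered"] for a in per_class_accuracy(cm)] == ["100.0%"] * 3


class TestRendering:
    @pytest.mark.parametrize(
        "frac, expected",
        [
            (61 / 73, "83.5%"),   # 83.56 truncates, does not round, to 83.5
            (26 / 61, "42.6%"),
            (25 / 37, "67.5%"),
            (1.0, "100.0%"),
        ],
    )
    def test_truncation_convention(self, frac, expected):
        assert truncate_percent(frac) == expected


class TestReferenceTables:
    def test_three_class_per_class_accuracies(self):
        cm = ConfusionMatrix(
            counts=np.array([[84, 12, 7], [6, 51, 4], [3, 5, 29]]),
            class_order=("NO_ROT", "ROT_LT_50", "ROT_GE_50"))
        assert [a["rendered"] for a in per_class_accuracy(cm)] == \
            ["81.5%", "83.6%", "78.3%"]

    def test_fixture_is_complete(self):
        fixture = load_reference_tables()
        assert set(fixture["tables"]) == {
            "1a", "1b", "1c", "2a", "2b", "2c",
            "3a", "3b", "3c", "4a", "4b", "4c"}

    def test_reproduction_consistency_flags(self):
        """Recomputed accuracies match the published strings everywhere the
        published table is internally consistent; the two known typos are
        flagged rather than silently matched."""
        report = reproduce_reference_tables()
        n_match = n_flagged = 0
        for tab in report["tables"].values():
            for row in tab["per_class"]:
                if row["published_inconsistent"]:
                    n_flagged += 1
                    assert not row["matches_published"]
                else:
                    n_match += 1
                    assert row["matches_published"]
        assert n_flagged == 2
        assert n_match == 28
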