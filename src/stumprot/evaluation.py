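"""Evaluation protocol: sq-thresholded detection matching and confusion tables.

Detection is scored by matching detector boxes to labeled boxes one-to-one in
descending score order: a detection claims the unmatched label with the
highest segmentation quality if that sq clears the threshold (0.5 by
default, with the comparison — ``>=`` or ``>`` — configurable); otherwise it
counts as a false positive, and labels left unclaimed are false negatives.

Classification is summarized as a square confusion matrix (rows true,
columns predicted) with a per-class accuracy column.  Exact fractions are
always carried; the rendered percentage strings follow the conventions of
the reference report this package reproduces — per-class accuracies
truncated to one decimal, detection precision rendered to the nearest
integer percent and recall truncated to integer percent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .segquality import BoundingBox, sq_score
from .simdata import LabeledScene, RotClass
from . import classifier as clf
from .classifier import LabeledCrop, TrainedClassifier, binary_label
from .detector import Detection, DetectorModel, detect

__all__ = [
    "DetectionEvalResult",
    "ConfusionMatrix",
    "match_detections",
    "confusion_matrix",
    "per_class_accuracy",
    "truncate_percent",
    "render_int_percent",
    "evaluate_pipeline",
    "load_reference_tables",
    "load_reference_detection_counts",
    "reproduce_reference_tables",
]


@dataclass(frozen=True)
class DetectionEvalResult:
    tp: int
    fp: int
    fn: int
    matches: tuple  # (detection_index, label_index, sq) triples

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")


def match_detections(detections: list[Detection], labels: list[BoundingBox],
                     sq_threshold: float = 0.5,
                     comparison: str = "ge") -> DetectionEvalResult:
    """Greedy one-to-one matching of detections to labeled boxes.

    Detections must arrive sorted by non-increasing score.  Ties on sq are
    broken toward the smaller label index; detections that clear the
    threshold on no unmatched label are false positives.
    """
    scores = [d.score for d in detections]
    if any(a < b for a, b in zip(scores, scores[1:])):
        raise ValueError("detections must be sorted by non-increasing score")
    meets = (lambda s: s >= sq_threshold) if comparison == "ge" else (lambda s: s > sq_threshold)
    unmatched = set(range(len(labels)))
    matches = []
    fp = 0
    for di, det in enumerate(detections):
        best_sq, best_li = -1.0, None
        for li in sorted(unmatched):
            s = sq_score(det.bbox, labels[li]).sq
            if s > best_sq:
                best_sq, best_li = s, li
        if best_li is not None and meets(best_sq):
            matches.append((di, best_li, best_sq))
            unmatched.remove(best_li)
        else:
            fp += 1
    return DetectionEvalResult(tp=len(matches), fp=fp, fn=len(unmatched),
                               matches=tuple(matches))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_order: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.shape[0] != len(self.class_order):
            raise ValueError("class_order length must match matrix size")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")


def confusion_matrix(true_labels, predicted_labels, class_order) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    index = {label: i for i, label in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def truncate_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction as a percentage truncated to ``decimals`` places."""
    scale = 10 ** decimals
    value = math.floor(fraction * 100 * scale + 1e-9) / scale
    return f"{value:.{decimals}f}%"


def render_int_percent(fraction: float, mode: str = "round") -> str:
    """Integer-percent rendering: ``round`` (nearest) or ``floor`` (truncate)."""
    pct = fraction * 100
    value = int(round(pct)) if mode == "round" else int(math.floor(pct + 1e-9))
    return f"{value}%"


def per_class_accuracy(cm: ConfusionMatrix) -> list[dict]:
    """Exact per-class accuracy fractions plus truncated-percent strings."""
    out = []
    counts = np.asarray(cm.counts)
    for i, label in enumerate(cm.class_order):
        row_sum = int(counts[i].sum())
        if row_sum == 0:
            raise ValueError(f"accuracy undefined for class {label!r} (empty row)")
        frac = int(counts[i, i]) / row_sum
        out.append({
            "class": getattr(label, "name", str(label)),
            "correct": int(counts[i, i]),
            "total": row_sum,
            "accuracy": frac,
            "rendered": truncate_percent(frac),
        })
    return out


# ---------------------------------------------------------------------------
# whole-pipeline evaluation
# ---------------------------------------------------------------------------


def _gt_crop(scene: LabeledScene, box: BoundingBox) -> np.ndarray:
    b = box.clipped(scene.image.shape[1], scene.image.shape[0])
    return scene.image[b.y_min:b.y_max, b.x_min:b.x_max]


def _label_of(ann, n_classes: int):
    return ann.rot_class if n_classes == 3 else binary_label(ann.rot_class)


def evaluate_pipeline(scenes: list[LabeledScene], detector: DetectorModel,
                      classifier: TrainedClassifier,
                      sq_threshold: float = 0.5,
                      comparison: str = "ge",
                      detections: list[list[Detection]] | None = None) -> dict:
    """Detection matching plus rot classification in both evaluation modes.

    ``manual`` mode classifies ground-truth box crops of every stump;
    ``detector_tp`` mode classifies only the crops of correctly detected
    stumps (the whole-application protocol).  Precomputed per-scene
    ``detections`` may be passed to avoid re-running the detector.  Returns a
    report dict with the detection counts and a confusion matrix per mode.
    """
    n_classes = classifier.spec.n_classes
    order = classifier.class_order
    if detections is None:
        detections = [detect(detector, scene.image) for scene in scenes]

    total = DetectionEvalResult(0, 0, 0, ())
    tp_crops, tp_true = [], []
    manual_crops, manual_true = [], []
    for scene, dets in zip(scenes, detections):
        labels = [ann.bbox for ann in scene.annotations]
        res = match_detections(dets, labels, sq_threshold, comparison)
        total = DetectionEvalResult(
            tp=total.tp + res.tp, fp=total.fp + res.fp, fn=total.fn + res.fn,
            matches=total.matches + res.matches,
        )
        for di, li, _sq in res.matches:
            tp_crops.append(_gt_crop(scene, dets[di].bbox))
            tp_true.append(_label_of(scene.annotations[li], n_classes))
        for ann in scene.annotations:
            manual_crops.append(_gt_crop(scene, ann.bbox))
            manual_true.append(_label_of(ann, n_classes))

    report = {
        "detection": {
            "tp": total.tp, "fp": total.fp, "fn": total.fn,
            "precision": total.precision, "recall": total.recall,
        },
        "modes": {},
    }
    for mode, crops, true in (("manual", manual_crops, manual_true),
                              ("detector_tp", tp_crops, tp_true)):
        if not crops:
            report["modes"][mode] = None
            continue
        pred = clf.predict_batch(classifier, crops)
        cm = confusion_matrix(true, pred, order)
        report["modes"][mode] = {
            "counts": cm.counts.tolist(),
            "class_order": [getattr(c, "name", str(c)) for c in order],
            "per_class": per_class_accuracy(cm),
        }
    return report


# ---------------------------------------------------------------------------
# shipped reference fixtures
# ---------------------------------------------------------------------------


def _load_fixture(name: str) -> dict:
    with resources.files("stumprot.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_reference_tables() -> dict:
    """The shipped reference confusion-matrix counts (keyed 1a..4c)."""
    return _load_fixture("tables_1_4_counts.json")


def load_reference_detection_counts() -> dict:
    """The shipped reference detection counts (TP/FP/FN on 201 test images)."""
    return _load_fixture("detector_counts.json")


def reproduce_reference_tables() -> dict:
    """Recompute every per-class accuracy and the detection precision/recall
    from the shipped reference counts.

    Returns, per table, the recomputed fractions and truncated-percent
    strings alongside the originally published strings; entries whose
    published string is internally inconsistent with its own count row are
    flagged so callers can tell recomputation mismatches from source typos.
    """
    fixture = load_reference_tables()
    report: dict = {"tables": {}}
    for key, tab in fixture["tables"].items():
        order = fixture["class_orders"][str(tab["n_classes"])]
        cm = ConfusionMatrix(counts=np.array(tab["counts"]),
                             class_order=tuple(order))
        rows = per_class_accuracy(cm)
        report["tables"][key] = {
            "approach": tab["approach"],
            "mode": tab["mode"],
            "per_class": [
                {
                    **row,
                    "published": tab["printed_accuracy"][i],
                    "published_inconsistent": tab["printed_inconsistent"][i],
                    "matches_published": row["rendered"] == tab["printed_accuracy"][i],
                }
                for i, row in enumerate(rows)
            ],
        }
    det = load_reference_detection_counts()
    res = DetectionEvalResult(tp=det["tp"], fp=det["fp"], fn=det["fn"], matches=())
    report["detection"] = {
        "tp": det["tp"], "fp": det["fp"], "fn": det["fn"],
        "precision": res.precision,
        "recall": res.recall,
        "precision_rendered": render_int_percent(res.precision, mode="round"),
        "recall_rendered": render_int_percent(res.recall, mode="floor"),
        "published_precision": det["printed_precision"],
        "published_recall": det["printed_recall"],
    }
    return report
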