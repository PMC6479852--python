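"""Desk-scale reference benchmarks for the detector and the classifiers.

Full-scale field results for this problem come from a thousand-image photo
campaign that cannot be bundled; these benchmarks substitute controlled
synthetic conditions at sizes a single CPU handles in minutes, and are the
basis of the package's acceptance checks:

* ``detector_benchmark`` — the *easy* detection setting: 60 training and 40
  test scenes, one unoccluded stump each, flat lighting.  Reported are
  precision and recall under sq-matching at threshold 0.5.
* ``classifier_benchmark`` — the three-grade classification setting: crops
  from single-stump scenes, class-balanced training at 160 crops per grade
  (the reference protocol's balancing size), held-out crops for testing, all
  three routes (BS, VS, VF) trained on the same sample.

Both are deterministic functions of their seed.
"""

from __future__ import annotations

import numpy as np

from . import classifier as clf
from .classifier import ClassifierSpec, LabeledCrop
from .detector import DetectorConfig, detect, train_detector
from .evaluation import confusion_matrix, match_detections, per_class_accuracy
from .features import pretrain_desk_backbone
from .simdata import RotClass, SceneParams, default_class_mix, generate_scenes

__all__ = ["detector_benchmark", "classifier_benchmark"]


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


#: Benchmark conditions: flat lighting, no occlusion, no shadow.
EASY_SCENE = SceneParams()

#: Crop-source conditions for the classification benchmark; smaller frames
#: with proportionally larger stumps keep rendering cheap without changing
#: the crops the classifiers actually see.
CROP_SCENE = SceneParams(image_height=192, image_width=192,
                         stump_radius_range=(0.22, 0.45))


def detector_benchmark(seed: int = 0, n_train: int = 60, n_test: int = 40,
                       config: DetectorConfig = DetectorConfig()) -> dict:
    """Train on ``n_train`` easy scenes, evaluate on ``n_test`` held-out ones.

    Returns TP/FP/FN with precision and recall at sq threshold 0.5, plus the
    matched-pair sq values.
    """
    s_train, s_test, s_fit = _derived_seeds(seed, 3)
    train = generate_scenes(default_class_mix(n_train), EASY_SCENE, seed=s_train)
    test = generate_scenes(default_class_mix(n_test), EASY_SCENE, seed=s_test)
    model = train_detector(train, config, seed=s_fit)
    tp = fp = fn = 0
    sqs: list[float] = []
    for scene in test:
        dets = detect(model, scene.image)
        res = match_detections(dets, [a.bbox for a in scene.annotations])
        tp, fp, fn = tp + res.tp, fp + res.fp, fn + res.fn
        sqs.extend(m[2] for m in res.matches)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "mean_matched_sq": float(np.mean(sqs)) if sqs else float("nan"),
        "n_train": n_train, "n_test": n_test,
    }


def _crops(scenes) -> list[LabeledCrop]:
    out = []
    for i, s in enumerate(scenes):
        b = s.bbox
        out.append(LabeledCrop(image=s.image[b.y_min:b.y_max, b.x_min:b.x_max],
                               rot_class=s.rot_class, source_id=i))
    return out


def classifier_benchmark(seed: int = 0, per_class: int = 160,
                         n_test_per_class: int = 35,
                         approaches: tuple[str, ...] = ("BS", "VS", "VF"),
                         n_classes: int = 3) -> dict:
    """Train BS/VS/VF on one balanced crop sample and grade held-out crops.

    Returns, per approach, the confusion matrix, per-class accuracies and
    overall accuracy on the held-out set.
    """
    s_train, s_test, s_bal, s_bb, s_fit = _derived_seeds(seed, 5)
    n_gen = per_class + 5  # headroom so balancing always succeeds
    train_scenes = generate_scenes((n_gen, n_gen, n_gen), CROP_SCENE, seed=s_train)
    test_scenes = generate_scenes(
        (n_test_per_class,) * 3, CROP_SCENE, seed=s_test)
    balanced = clf.balance_classes(_crops(train_scenes), per_class, seed=s_bal)
    test_crops = _crops(test_scenes)
    backbone = pretrain_desk_backbone(seed=s_bb)

    if n_classes == 3:
        truth = [c.rot_class for c in test_crops]
    else:
        truth = [clf.binary_label(c.rot_class) for c in test_crops]

    out: dict = {"per_class_train": per_class, "n_test": len(test_crops),
                 "approaches": {}}
    for approach in approaches:
        spec = ClassifierSpec(approach=approach, n_classes=n_classes,
                              balance_per_class=per_class)
        model = clf.train(spec, balanced, seed=s_fit, backbone=backbone)
        preds = clf.predict_batch(model, [c.image for c in test_crops])
        cm = confusion_matrix(truth, preds, model.class_order)
        accs = per_class_accuracy(cm)
        out["approaches"][approach] = {
            "counts": cm.counts.tolist(),
            "per_class_accuracy": {a["class"]: a["accuracy"] for a in accs},
            "overall_accuracy": float(np.trace(cm.counts) / cm.counts.sum()),
        }
    return out
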