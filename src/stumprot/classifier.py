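"""Rot-severity classification of stump crops: three interchangeable routes.

* **BS** — bag-of-visual-words histograms into a multi-class SVM.
* **VS** — CNN penultimate-layer features into a multi-class SVM.
* **VF** — the CNN itself, fine-tuned end-to-end after replacing its
  classification head with a fresh FC-64 / ReLU / FC-n / softmax stack whose
  learning rate is boosted relative to the pretrained trunk.

All three train on a class-balanced sample (the reference protocol balances
at 160 crops per class, the size of its smallest class) and support either
two classes (rot absent / present) or the three severity grades.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .features import DeskBackbone, Vocabulary, build_vocabulary, encode_bof, \
    extract_descriptors, pretrain_desk_backbone
from .nnet import Dense, Net, ReLU, sgdm_fit
from .simdata import RotClass

__all__ = [
    "FinetuneSpec",
    "ClassifierSpec",
    "LabeledCrop",
    "TrainedClassifier",
    "CLASS_ORDER_3",
    "CLASS_ORDER_2",
    "binary_label",
    "balance_classes",
    "train",
    "predict",
    "predict_batch",
]

CLASS_ORDER_3 = (RotClass.NO_ROT, RotClass.ROT_LT_50, RotClass.ROT_GE_50)
CLASS_ORDER_2 = ("NO_ROT", "ROT")


def binary_label(cls: RotClass) -> str:
    """Collapse the three severity grades to rot absent / present."""
    return "NO_ROT" if cls is RotClass.NO_ROT else "ROT"


@dataclass(frozen=True)
class FinetuneSpec:
    """Fine-tuning hyperparameters for the VF route.

    Defaults are the desk profile matched to the numpy backbone; the
    documented full-scale recipe (batch 16, initial lr 1e-4, 300 epochs on a
    pretrained 19-layer backbone) is available via :meth:`full_scale`.
    """

    batch_size: int = 16
    initial_lr: float = 0.01
    max_epochs: int = 30
    lr_boost_new_layers: float = 10.0
    new_head: tuple[str, ...] = ("FC-64", "ReLU", "FC-n", "softmax", "classification")

    @classmethod
    def full_scale(cls) -> "FinetuneSpec":
        return cls(batch_size=16, initial_lr=1e-4, max_epochs=300)


@dataclass(frozen=True)
class ClassifierSpec:
    approach: str = "VF"  # BS | VS | VF
    n_classes: int = 3
    balance_per_class: int = 160
    svm_kernel: str = "linear"
    bof_k: int = 500
    finetune: FinetuneSpec = field(default_factory=FinetuneSpec)

    def __post_init__(self) -> None:
        if self.approach not in ("BS", "VS", "VF"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.balance_per_class < 1:
            raise ValueError("balance_per_class must be >= 1")

    @property
    def class_order(self) -> tuple:
        return CLASS_ORDER_3 if self.n_classes == 3 else CLASS_ORDER_2


@dataclass(frozen=True)
class LabeledCrop:
    """A stump crop with its severity grade (and optional provenance)."""

    image: np.ndarray
    rot_class: RotClass
    source_id: int | None = None


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    class_order: tuple
    vocab: Vocabulary | None = None
    svm: object | None = None
    scaler: StandardScaler | None = None
    backbone: DeskBackbone | None = None
    net: Net | None = None


def balance_classes(crops: list[LabeledCrop], per_class: int,
                    seed: int = 0) -> list[LabeledCrop]:
    """Draw exactly ``per_class`` crops per class, without replacement.

    Raises when any class has fewer than ``per_class`` members.  Selection is
    deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[RotClass, list[LabeledCrop]] = {}
    for crop in crops:
        by_class.setdefault(crop.rot_class, []).append(crop)
    out: list[LabeledCrop] = []
    for cls in sorted(by_class, key=int):
        members = by_class[cls]
        if len(members) < per_class:
            raise ValueError(
                f"class {cls.name} has {len(members)} crops, need {per_class}")
        idx = rng.choice(len(members), size=per_class, replace=False)
        out.extend(members[i] for i in idx)
    return out


def _labels_for(spec: ClassifierSpec, crops: list[LabeledCrop]) -> np.ndarray:
    order = spec.class_order
    if spec.n_classes == 3:
        return np.array([order.index(c.rot_class) for c in crops])
    return np.array([order.index(binary_label(c.rot_class)) for c in crops])


def _make_svm(spec: ClassifierSpec, seed: int):
    if spec.svm_kernel == "linear":
        return LinearSVC(random_state=seed % (2**31))
    return SVC(kernel=spec.svm_kernel, random_state=seed % (2**31))


def train(spec: ClassifierSpec, train_crops: list[LabeledCrop], seed: int = 0,
          backbone: DeskBackbone | None = None) -> TrainedClassifier:
    """Train one classification route on (balanced) labeled crops.

    The CNN routes reuse a pretrained desk backbone when one is supplied;
    otherwise one is pretrained on the auxiliary synthetic task first.
    """
    if not train_crops:
        raise ValueError("empty training set")
    present = {c.rot_class for c in train_crops}
    if spec.n_classes == 3 and len(present) < 3:
        raise ValueError("three-class training requires crops of all three grades")
    y = _labels_for(spec, train_crops)
    model = TrainedClassifier(spec=spec, class_order=spec.class_order)
    rng = np.random.default_rng(seed)

    if spec.approach == "BS":
        desc_sets = [extract_descriptors(c.image) for c in train_crops]
        model.vocab = build_vocabulary(desc_sets, k=spec.bof_k,
                                       seed=int(rng.integers(2**31)))
        feats = np.stack([_bof_from_descriptors(d, model.vocab)
                          for d in desc_sets])
        model.svm = _make_svm(spec, seed)
        model.svm.fit(feats, y)
        return model

    if backbone is None:
        backbone = pretrain_desk_backbone(seed=int(rng.integers(2**31)))
    model.backbone = backbone

    if spec.approach == "VS":
        feats = backbone.features([c.image for c in train_crops])
        model.scaler = StandardScaler().fit(feats)
        model.svm = _make_svm(spec, seed)
        model.svm.fit(model.scaler.transform(feats), y)
        return model

    # VF: clone the pretrained trunk, attach a fresh boosted head, train all
    ft = spec.finetune
    head_rng = np.random.default_rng(int(rng.integers(2**31)))
    trunk = copy.deepcopy(backbone.body_layers())
    head = [
        Dense(DeskBackbone.PENULTIMATE_WIDTH, 64, rng=head_rng,
              lr_scale=ft.lr_boost_new_layers),
        ReLU(),
        Dense(64, spec.n_classes, rng=head_rng,
              lr_scale=ft.lr_boost_new_layers),
    ]
    net = Net(trunk + head)
    x = backbone.preprocess([c.image for c in train_crops])
    sgdm_fit(net, x, y, [(ft.initial_lr, ft.max_epochs)], ft.batch_size,
             rng=np.random.default_rng(int(rng.integers(2**31))))
    model.net = net
    return model


def _bof_from_descriptors(desc: np.ndarray, vocab: Vocabulary) -> np.ndarray:
    from sklearn.metrics import pairwise_distances_argmin

    hist = np.zeros(vocab.k)
    if len(desc):
        idx = pairwise_distances_argmin(desc, vocab.centers)
        np.add.at(hist, idx, 1.0)
        hist /= hist.sum()
    return hist


def predict_batch(model: TrainedClassifier, crops: list[np.ndarray]) -> list:
    """Hard labels (drawn from ``model.class_order``) for a list of crops."""
    spec = model.spec
    if spec.approach == "BS":
        if model.svm is None:
            raise RuntimeError("classifier is untrained")
        feats = np.stack([encode_bof(c, model.vocab).values for c in crops])
        idx = model.svm.predict(feats)
    elif spec.approach == "VS":
        if model.svm is None:
            raise RuntimeError("classifier is untrained")
        feats = model.scaler.transform(model.backbone.features(crops))
        idx = model.svm.predict(feats)
    else:
        if model.net is None:
            raise RuntimeError("classifier is untrained")
        x = model.backbone.preprocess(crops)
        idx = model.net.predict_proba(x).argmax(axis=1)
    return [model.class_order[i] for i in idx]


def predict(model: TrainedClassifier, crop: np.ndarray):
    """Hard label for a single crop (argmax of softmax for the VF route)."""
    return predict_batch(model, [crop])[0]


def save_classifier(model: TrainedClassifier, path) -> None:
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_classifier(path) -> TrainedClassifier:
    import pickle

    with open(path, "rb") as fh:
        return pickle.load(fh)
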