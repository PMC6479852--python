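"""Fixed-length image features: bag-of-visual-words and CNN activations.

Two interchangeable feature routes feed the rot classifiers:

* **Bag of features (BoF / bag of visual words).**  Local scale-invariant
  descriptors are extracted from each crop, quantized against a k-means
  vocabulary (k = 500 by default) and histogrammed; the histogram is
  normalized to sum 1 so crops of different sizes are comparable.  The
  descriptor is pluggable; the default is SIFT (scikit-image), a patent-free
  member of the same scale-invariant descriptor family as SURF, and the
  choice is recorded in ``Vocabulary.descriptor_kind``.

* **CNN penultimate-layer activations.**  The activations of the last fully
  connected layer before the classification head serve as a generic feature
  vector (the "FC-7" recipe: 4096-wide on a full 19-layer backbone).  The
  backbone contract here is met by a desk-scale CNN — three conv blocks and
  an FC-128 penultimate layer — pretrained on an auxiliary synthetic task
  (stump-surface vs forest-floor discrimination), so the whole pipeline runs
  self-contained; a full pretrained backbone can be slotted in behind the
  same interface when its weights are available locally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import SIFT
from skimage.transform import resize as _sk_resize
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

from .nnet import Conv2D, Dense, Flatten, MaxPool2, Net, ReLU, sgdm_fit
from .segquality import BoundingBox
from .simdata import SceneParams, generate_scenes

__all__ = [
    "Vocabulary",
    "FeatureVector",
    "extract_descriptors",
    "build_vocabulary",
    "encode_bof",
    "DeskBackbone",
    "pretrain_desk_backbone",
    "extract_cnn_features",
]


@dataclass(frozen=True)
class Vocabulary:
    """k-means visual-word vocabulary over local descriptors."""

    centers: np.ndarray  # k x d
    descriptor_kind: str = "sift"

    def __post_init__(self) -> None:
        if self.centers.ndim != 2 or self.centers.shape[0] < 2:
            raise ValueError("vocabulary needs at least 2 centers")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("vocabulary centers must be finite")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez(Path(path), centers=self.centers,
                 descriptor_kind=np.array(self.descriptor_kind))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        with np.load(Path(path)) as data:
            return cls(centers=data["centers"],
                       descriptor_kind=str(data["descriptor_kind"]))


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    source: str  # "BOF" or "CNN_PENULTIMATE"


def extract_descriptors(image: np.ndarray) -> np.ndarray:
    """Scale-invariant local descriptors of an image, shape (n, d).

    Returns an empty ``(0, 128)`` array when no keypoints are found (e.g. on
    a uniform image).
    """
    img = np.asarray(image)
    gray = rgb2gray(img) if img.ndim == 3 else img.astype(float)
    sift = SIFT()
    try:
        sift.detect_and_extract(gray)
    except RuntimeError:  # no keypoints found
        return np.empty((0, 128), dtype=float)
    if sift.descriptors is None or len(sift.descriptors) == 0:
        return np.empty((0, 128), dtype=float)
    return sift.descriptors.astype(float)


def extract_keypoints_and_descriptors(image: np.ndarray):
    """Keypoint coordinates (n, 2; row, col) alongside descriptors."""
    img = np.asarray(image)
    gray = rgb2gray(img) if img.ndim == 3 else img.astype(float)
    sift = SIFT()
    try:
        sift.detect_and_extract(gray)
    except RuntimeError:
        return np.empty((0, 2)), np.empty((0, 128))
    return sift.keypoints.astype(float), sift.descriptors.astype(float)


def build_vocabulary(descriptor_sets, k: int = 500, seed: int = 0,
                     descriptor_kind: str = "sift",
                     max_fit_descriptors: int = 30000) -> Vocabulary:
    """Cluster pooled descriptors into ``k`` visual words with k-means.

    Raises when fewer than ``k`` descriptors are available.  Large pools are
    subsampled (deterministically) before fitting to keep clustering cheap.
    """
    pool = np.concatenate([d for d in descriptor_sets if len(d)], axis=0) \
        if any(len(d) for d in descriptor_sets) else np.empty((0, 128))
    if len(pool) < k:
        raise ValueError(f"need at least k={k} descriptors, got {len(pool)}")
    rng = np.random.default_rng(seed)
    if len(pool) > max_fit_descriptors:
        pool = pool[rng.choice(len(pool), max_fit_descriptors, replace=False)]
    km = KMeans(n_clusters=k, n_init=1, max_iter=50, random_state=seed % (2**31))
    km.fit(pool)
    return Vocabulary(centers=km.cluster_centers_, descriptor_kind=descriptor_kind)


def encode_bof(image: np.ndarray, vocab: Vocabulary) -> FeatureVector:
    """Histogram of nearest-visual-word assignments, normalized to sum 1.

    A crop with no detectable local structure encodes as the all-zero vector
    (the documented degenerate case).
    """
    desc = extract_descriptors(image)
    hist = np.zeros(vocab.k, dtype=float)
    if len(desc):
        if desc.shape[1] != vocab.d:
            raise ValueError(
                f"descriptor dim {desc.shape[1]} != vocabulary dim {vocab.d}")
        idx = pairwise_distances_argmin(desc, vocab.centers)
        np.add.at(hist, idx, 1.0)
        hist /= hist.sum()
    return FeatureVector(values=hist, source="BOF")


# ---------------------------------------------------------------------------
# desk-scale CNN backbone
# ---------------------------------------------------------------------------


class DeskBackbone:
    """Small CNN backbone exposing penultimate-layer features.

    Architecture (input 48 x 48 x 3): three conv blocks (16, 32, 64 filters,
    each 3x3 conv + ReLU + 2x2 max pool), then FC-128 + ReLU (the penultimate
    feature layer) and a task head.  ``features`` returns the 128-wide
    penultimate activations, the desk-scale analogue of a 4096-wide FC-7.
    """

    INPUT_SIZE = 48
    PENULTIMATE_WIDTH = 128

    def __init__(self, net: Net, n_out: int):
        self.net = net
        self.n_out = n_out

    @classmethod
    def build(cls, n_out: int, seed: int = 0) -> "DeskBackbone":
        rng = np.random.default_rng(seed)
        s = cls.INPUT_SIZE
        # 48 -> 46 -> 23 -> 21 -> 10 -> 8 -> 4
        flat = 4 * 4 * 64
        net = Net([
            Conv2D(3, 16, 3, rng=rng), ReLU(), MaxPool2(),
            Conv2D(16, 32, 3, rng=rng), ReLU(), MaxPool2(),
            Conv2D(32, 64, 3, rng=rng), ReLU(), MaxPool2(),
            Flatten(),
            Dense(flat, cls.PENULTIMATE_WIDTH, rng=rng), ReLU(),
            Dense(cls.PENULTIMATE_WIDTH, n_out, rng=rng),
        ])
        return cls(net, n_out)

    def preprocess(self, images) -> np.ndarray:
        """Resize crops to the backbone input and scale to [-0.5, 0.5]."""
        s = self.INPUT_SIZE
        out = np.empty((len(images), s, s, 3), dtype=np.float32)
        for i, im in enumerate(images):
            im = np.asarray(im)
            if im.shape[:2] != (s, s):
                im = _sk_resize(im, (s, s), order=1, preserve_range=True,
                                anti_aliasing=True)
            out[i] = im.astype(np.float32)
        return out / 255.0 - 0.5

    def features(self, images) -> np.ndarray:
        """Penultimate-layer activations, one row per crop."""
        x = self.preprocess(images)
        return self.net.penultimate(x, n_tail=1)

    def body_layers(self) -> list:
        """Layers up to and including the penultimate ReLU (shared trunk)."""
        return self.net.layers[:-1]


def pretrain_desk_backbone(seed: int = 0, n_scenes: int = 60,
                           epochs: int = 6) -> DeskBackbone:
    """Pretrain the desk backbone on an auxiliary synthetic task.

    The auxiliary task — telling stump-surface crops from forest-floor
    crops rendered by the scene generator — plays the role that large-scale
    natural-image pretraining plays for a full backbone: it teaches the
    trunk generic wood/clutter texture filters before any rot labels are
    seen.
    """
    rng = np.random.default_rng(seed)
    params = SceneParams(image_height=160, image_width=160,
                         stump_radius_range=(0.18, 0.42),
                         lighting_gain=(0.8, 1.2), shadow=True,
                         occlusion_fraction=0.2)
    third = n_scenes // 3
    scenes = generate_scenes((n_scenes - 2 * third, third, third), params,
                             seed=int(rng.integers(2**31)))
    backbone = DeskBackbone.build(n_out=2, seed=int(rng.integers(2**31)))
    crops, labels = [], []
    for scene in scenes:
        b = scene.bbox
        crops.append(scene.image[b.y_min:b.y_max, b.x_min:b.x_max])
        labels.append(1)
        # a background crop of similar size that misses the stump
        h, w = scene.image.shape[:2]
        for _try in range(30):
            bw = min(b.width, w - 1)
            bh = min(b.height, h - 1)
            x0 = int(rng.uniform(0, w - bw))
            y0 = int(rng.uniform(0, h - bh))
            cand = BoundingBox(x0, y0, x0 + bw, y0 + bh)
            if (cand.x_max <= b.x_min or cand.x_min >= b.x_max
                    or cand.y_max <= b.y_min or cand.y_min >= b.y_max):
                crops.append(scene.image[y0:y0 + bh, x0:x0 + bw])
                labels.append(0)
                break
    x = backbone.preprocess(crops)
    y = np.array(labels)
    sgdm_fit(backbone.net, x, y, [(0.01, epochs)], batch_size=16, rng=rng)
    return backbone


def extract_cnn_features(image: np.ndarray, backbone: DeskBackbone) -> FeatureVector:
    """Penultimate-layer feature vector for one crop."""
    if backbone is None or backbone.net is None:
        raise RuntimeError("backbone is uninitialized")
    vec = backbone.features([image])[0]
    return FeatureVector(values=vec, source="CNN_PENULTIMATE")
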