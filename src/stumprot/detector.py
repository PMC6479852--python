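"""Two-stage stump detector: multi-scale window proposals scored by a CNN.

The detector follows the classic two-stage recipe: class-agnostic candidate
boxes are generated over a frame standardized to 300 x 400 pixels, each
candidate is resampled to a 32 x 32 patch and scored stump-vs-background by a
small CNN (two 3x3 conv layers of 32 filters with ReLU, one 2x2 max pool,
FC-64, ReLU, FC-2, softmax), and surviving boxes go through non-maximum
suppression.  Suppression and evaluation both use the segmentation-quality
score ``sq`` rather than IoU.

Two networks with this same architecture share the work, mirroring the
proposal/detection split of two-stage detectors: a *proposal* network,
trained on loosely overlapping windows, finds seed regions in a coarse
multi-scale sliding-window sweep; a *detection* network, trained only on
tight boxes (with partial, interior and over-large windows as explicit
negatives), scores a dense local offset/scale grid around each seed so the
final box is both confident and well-localized.  The historical full-scale
training recipe (four-step alternating optimization, sgdm, mini-batch 1,
learning rates 1e-5/1e-5/1e-6/1e-6 over 20/20/20/10 epochs) is carried as
the documented ``full_scale`` schedule; the desk profile used throughout
the tests trains both CNNs directly with a shorter schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .nnet import Conv2D, Dense, Flatten, MaxPool2, Net, ReLU, sgdm_fit
from .segquality import BoundingBox, intersect_area, sq_score
from .simdata import LabeledScene

__all__ = [
    "DetectorConfig",
    "Detection",
    "DetectorModel",
    "resize_for_detection",
    "train_detector",
    "detect",
    "nms",
    "save_model",
    "load_model",
]

#: The documented full-scale four-step schedule: (learning rate, epochs).
FULL_SCALE_SCHEDULE = ((1e-5, 20), (1e-5, 20), (1e-6, 20), (1e-6, 10))


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture, training and inference settings of the stump detector."""

    input_size: tuple[int, int] = (300, 400)  # rows, cols
    patch_size: int = 32
    conv_filters: int = 32
    fc_hidden: int = 64
    n_classes: int = 2  # stump, background
    solver: str = "sgdm"
    mini_batch: int = 32
    train_schedule: tuple[tuple[float, int], ...] = ((0.02, 14), (0.004, 7))
    momentum: float = 0.9
    score_threshold: float = 0.5
    nms_sq_threshold: float = 0.3
    # boxes smaller than this on either side are discarded: no stump in the
    # modeled size range can appear that small in the standardized frame
    min_detection_size: int = 30
    # proposal sweep: a coarse multi-scale grid finds seed boxes, a dense
    # local grid around each seed refines position and scale
    proposal_min_size: int = 40
    proposal_max_size: int = 232
    proposal_scale_step: float = 1.4
    proposal_aspects: tuple[float, ...] = (1.0, 0.8)
    proposal_stride_fraction: float = 0.45
    seed_score_threshold: float = 0.3
    max_seeds: int = 8
    # round 1 sweeps a wide offset/scale grid around each seed; later
    # rounds narrow in around the best box found so far
    refine_wide_scales: tuple[float, ...] = (0.7, 0.85, 1.0, 1.18, 1.4)
    refine_wide_offsets: tuple[float, ...] = (-0.2, 0.0, 0.2)
    refine_narrow_scales: tuple[float, ...] = (0.9, 1.0, 1.1)
    refine_narrow_offsets: tuple[float, ...] = (-0.08, 0.0, 0.08)
    refine_rounds: int = 3
    # after initial training, false alarms mined from training scenes are
    # fed back as negatives and the detection net is trained a little more
    hard_negative_rounds: int = 1
    hard_negative_scenes: int = 30
    hard_negative_schedule: tuple[tuple[float, int], ...] = ((0.008, 4),)
    # training-patch sampling
    pos_per_scene: int = 10
    neg_per_scene: int = 16

    def __post_init__(self) -> None:
        if self.patch_size >= min(self.input_size):
            raise ValueError("patch must be smaller than the input frame")
        if not (0 < self.score_threshold < 1 and 0 < self.nms_sq_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def full_scale(cls) -> "DetectorConfig":
        """The documented full-scale profile (sgdm, mini-batch 1, 4 phases)."""
        return cls(mini_batch=1, train_schedule=FULL_SCALE_SCHEDULE)


@dataclass(frozen=True)
class Detection:
    """One scored detector output box (in the standardized frame)."""

    bbox: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1]: {self.score}")


class DetectorModel:
    """Trained proposal + detection CNN pair plus their configuration."""

    def __init__(self, config: DetectorConfig,
                 proposal_net: Net | None = None,
                 detection_net: Net | None = None):
        self.config = config
        self.proposal_net = proposal_net
        self.detection_net = detection_net

    @property
    def net(self) -> Net | None:
        """The final scoring (detection) network."""
        return self.detection_net

    @property
    def trained(self) -> bool:
        return self.proposal_net is not None and self.detection_net is not None


def resize_for_detection(image: np.ndarray,
                         input_size: tuple[int, int] = (300, 400)):
    """Resample an RGB image to the detector frame (rows, cols).

    Returns ``(resized, (sx, sy))`` where multiplying frame x/y coordinates
    by ``sx``/``sy`` maps boxes back to the original image.  The resize is
    anisotropic: aspect ratio is not preserved.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    th, tw = input_size
    sx, sy = w / tw, h / th
    if (h, w) == (th, tw):
        return image, (1.0, 1.0)
    out = _sk_resize(image, (th, tw), order=1, preserve_range=True,
                     anti_aliasing=(h > th or w > tw))
    return out.astype(image.dtype), (sx, sy)


def _build_net(config: DetectorConfig, rng: np.random.Generator) -> Net:
    p = config.patch_size
    f = config.conv_filters
    after_conv = p - 4       # two valid 3x3 convs
    after_pool = after_conv // 2
    flat = after_pool * after_pool * f
    return Net([
        Conv2D(3, f, 3, rng=rng),
        ReLU(),
        Conv2D(f, f, 3, rng=rng),
        ReLU(),
        MaxPool2(),
        Flatten(),
        Dense(flat, config.fc_hidden, rng=rng),
        ReLU(),
        Dense(config.fc_hidden, config.n_classes, rng=rng),
    ])


def _crop_resize(image: np.ndarray, box: BoundingBox, size: int) -> np.ndarray:
    """Nearest-neighbour crop-and-resize of a box to size x size x 3."""
    ys = box.y_min + ((np.arange(size) + 0.5) * box.height / size).astype(int)
    xs = box.x_min + ((np.arange(size) + 0.5) * box.width / size).astype(int)
    ys = np.clip(ys, 0, image.shape[0] - 1)
    xs = np.clip(xs, 0, image.shape[1] - 1)
    return image[np.ix_(ys, xs)]


def _normalize(patches: np.ndarray) -> np.ndarray:
    return (patches.astype(np.float32) / 255.0) - 0.5


def _scene_frame(scene: LabeledScene, config: DetectorConfig):
    """Scene image and ground-truth boxes in the detector frame."""
    img, (sx, sy) = resize_for_detection(scene.image, config.input_size)
    boxes = []
    for ann in scene.annotations:
        b = ann.bbox
        if (sx, sy) == (1.0, 1.0):
            boxes.append(b)
        else:
            boxes.append(BoundingBox(
                x_min=int(b.x_min / sx), y_min=int(b.y_min / sy),
                x_max=max(int(b.x_max / sx), int(b.x_min / sx) + 1),
                y_max=max(int(b.y_max / sy), int(b.y_min / sy) + 1),
            ))
    return img, boxes


def _sample_proposal_patches(scenes, config: DetectorConfig, rng):
    """Loose objectness patches: any window with sq >= 0.55 against a stump
    is positive, pure background is negative."""
    th, tw = config.input_size
    pos, neg = [], []
    for scene in scenes:
        img, gt_boxes = _scene_frame(scene, config)
        for gt in gt_boxes:
            pos.append(_crop_resize(img, gt.clipped(tw, th), config.patch_size))
            for _ in range(config.pos_per_scene - 1):
                for _try in range(25):
                    fs = rng.uniform(0.7, 1.4)
                    dx = int(rng.uniform(-0.22, 0.22) * gt.width)
                    dy = int(rng.uniform(-0.22, 0.22) * gt.height)
                    w = max(int(gt.width * fs), 8)
                    h = max(int(gt.height * fs), 8)
                    cx = (gt.x_min + gt.x_max) // 2 + dx
                    cy = (gt.y_min + gt.y_max) // 2 + dy
                    cand = BoundingBox(cx - w // 2, cy - h // 2,
                                       cx - w // 2 + w,
                                       cy - h // 2 + h).clipped(tw, th)
                    if sq_score(cand, gt).sq >= 0.55:
                        pos.append(_crop_resize(img, cand, config.patch_size))
                        break
        got = 0
        for _try in range(40 * config.neg_per_scene):
            if got >= config.neg_per_scene:
                break
            w = int(rng.uniform(config.proposal_min_size, config.proposal_max_size))
            h = int(w * rng.uniform(0.7, 1.0))
            x0 = int(rng.uniform(0, tw - w))
            y0 = int(rng.uniform(0, th - h))
            cand = BoundingBox(x0, y0, x0 + w, y0 + h)
            if all(sq_score(cand, gt).sq < 0.25 for gt in gt_boxes):
                neg.append(_crop_resize(img, cand, config.patch_size))
                got += 1
    x = np.stack(pos + neg)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return _normalize(x), y


def _sample_detection_patches(scenes, config: DetectorConfig, rng):
    th, tw = config.input_size
    pos, neg = [], []
    for scene in scenes:
        img, gt_boxes = _scene_frame(scene, config)
        for gt in gt_boxes:
            pos.append(_crop_resize(img, gt.clipped(tw, th), config.patch_size))
            # jittered positives: tight boxes only, so high scores imply
            # full-extent localization
            for _ in range(config.pos_per_scene - 1):
                for _try in range(20):
                    fs = rng.uniform(0.90, 1.12)
                    dx = int(rng.uniform(-0.08, 0.08) * gt.width)
                    dy = int(rng.uniform(-0.08, 0.08) * gt.height)
                    w = max(int(gt.width * fs), 8)
                    h = max(int(gt.height * fs), 8)
                    cx = (gt.x_min + gt.x_max) // 2 + dx
                    cy = (gt.y_min + gt.y_max) // 2 + dy
                    cand = BoundingBox(cx - w // 2, cy - h // 2,
                                       cx - w // 2 + w, cy - h // 2 + h).clipped(tw, th)
                    if sq_score(cand, gt).sq >= 0.70:
                        pos.append(_crop_resize(img, cand, config.patch_size))
                        break
        # negatives come in three structured flavours so the CNN learns
        # "whole stump at the right scale", not merely "wood texture":
        for gt in gt_boxes:
            gcx, gcy = (gt.x_min + gt.x_max) // 2, (gt.y_min + gt.y_max) // 2
            # (b) interior sub-windows: wood texture without the stump rim
            for _ in range(3):
                f = rng.uniform(0.25, 0.5)
                w = max(int(gt.width * f), 8)
                h = max(int(gt.height * f), 8)
                dx = int(rng.uniform(-0.15, 0.15) * gt.width)
                dy = int(rng.uniform(-0.15, 0.15) * gt.height)
                cand = BoundingBox(gcx + dx - w // 2, gcy + dy - h // 2,
                                   gcx + dx - w // 2 + w,
                                   gcy + dy - h // 2 + h).clipped(tw, th)
                neg.append(_crop_resize(img, cand, config.patch_size))
            # (b') off-centre part windows: cover at most half the stump box
            # while lying mostly on it — duplicate-detection lookalikes
            got_parts = 0
            for _try in range(60):
                if got_parts >= 5:
                    break
                f = rng.uniform(0.35, 0.72)
                w = max(int(gt.width * f), 8)
                h = max(int(gt.height * f), 8)
                cx = int(rng.uniform(gt.x_min, gt.x_max))
                cy = int(rng.uniform(gt.y_min, gt.y_max))
                cand = BoundingBox(cx - w // 2, cy - h // 2,
                                   cx - w // 2 + w,
                                   cy - h // 2 + h).clipped(tw, th)
                o = intersect_area(cand, gt)
                if o / gt.area <= 0.45 and o / cand.area >= 0.6:
                    neg.append(_crop_resize(img, cand, config.patch_size))
                    got_parts += 1
            # (c) over-large containing windows: stump too small in frame
            for _ in range(3):
                f = rng.uniform(1.7, 2.6)
                w = min(int(gt.width * f), tw)
                h = min(int(gt.height * f), th)
                dx = int(rng.uniform(-0.2, 0.2) * gt.width)
                dy = int(rng.uniform(-0.2, 0.2) * gt.height)
                cand = BoundingBox(gcx + dx - w // 2, gcy + dy - h // 2,
                                   gcx + dx - w // 2 + w,
                                   gcy + dy - h // 2 + h).clipped(tw, th)
                if cand.width >= 1.5 * gt.width or cand.height >= 1.5 * gt.height:
                    neg.append(_crop_resize(img, cand, config.patch_size))
        # (a) pure background windows away from every stump
        n_img_neg = config.neg_per_scene
        got = 0
        for _try in range(40 * n_img_neg):
            if got >= n_img_neg:
                break
            w = int(rng.uniform(config.proposal_min_size, config.proposal_max_size))
            h = int(w * rng.uniform(0.7, 1.0))
            x0 = int(rng.uniform(0, tw - w))
            y0 = int(rng.uniform(0, th - h))
            cand = BoundingBox(x0, y0, x0 + w, y0 + h)
            if all(sq_score(cand, gt).sq < 0.25 for gt in gt_boxes):
                neg.append(_crop_resize(img, cand, config.patch_size))
                got += 1
    x = np.stack(pos + neg)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return _normalize(x), y


def train_detector(training_scenes, config: DetectorConfig = DetectorConfig(),
                   seed: int = 0) -> DetectorModel:
    """Train the proposal and detection CNNs on patches from labeled scenes.

    Deterministic given ``seed`` (up to floating-point reduction order).
    Raises on an empty training set or degenerate ground-truth boxes.
    """
    scenes = list(training_scenes)
    if not scenes:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    xp, yp = _sample_proposal_patches(scenes, config, rng)
    proposal_net = _build_net(config, rng)
    sgdm_fit(proposal_net, xp, yp, list(config.train_schedule),
             config.mini_batch, rng, momentum=config.momentum)
    xd, yd = _sample_detection_patches(scenes, config, rng)
    detection_net = _build_net(config, rng)
    sgdm_fit(detection_net, xd, yd, list(config.train_schedule),
             config.mini_batch, rng, momentum=config.momentum)
    model = DetectorModel(config, proposal_net, detection_net)

    # hard-negative mining: run the full detector on training scenes and
    # feed confident false alarms back as negatives
    for _round in range(config.hard_negative_rounds):
        mined = []
        for scene in scenes[: config.hard_negative_scenes]:
            img, gt_boxes = _scene_frame(scene, config)
            for det in detect(model, scene.image):
                worst = max((sq_score(det.bbox, gt).sq for gt in gt_boxes),
                            default=0.0)
                if worst < 0.55:
                    mined.append(_crop_resize(img, det.bbox, config.patch_size))
        if not mined:
            break
        xm = np.concatenate([xd, _normalize(np.stack(mined))])
        ym = np.concatenate([yd, np.zeros(len(mined), dtype=int)])
        sgdm_fit(detection_net, xm, ym, list(config.hard_negative_schedule),
                 config.mini_batch, rng, momentum=config.momentum)
        xd, yd = xm, ym
    return model


def _proposal_grid(config: DetectorConfig):
    """All (box, window-shape) proposals for the standardized frame."""
    th, tw = config.input_size
    sizes = []
    s = float(config.proposal_min_size)
    while s <= config.proposal_max_size:
        sizes.append(int(round(s)))
        s *= config.proposal_scale_step
    specs = []
    for w in sizes:
        for aspect in config.proposal_aspects:
            h = int(round(w * aspect))
            if h > th or w > tw:
                continue
            stride_x = max(int(w * config.proposal_stride_fraction), 4)
            stride_y = max(int(h * config.proposal_stride_fraction), 4)
            x0s = np.arange(0, tw - w + 1, stride_x)
            y0s = np.arange(0, th - h + 1, stride_y)
            if x0s[-1] != tw - w:
                x0s = np.append(x0s, tw - w)
            if y0s[-1] != th - h:
                y0s = np.append(y0s, th - h)
            specs.append((w, h, x0s, y0s))
    return specs


def _gather_patches(img: np.ndarray, w: int, h: int, x0s, y0s, size: int):
    """Vectorized nearest-neighbour extraction of all windows of one shape."""
    off_y = ((np.arange(size) + 0.5) * h / size).astype(int)
    off_x = ((np.arange(size) + 0.5) * w / size).astype(int)
    ys = y0s[:, None] + off_y[None, :]          # ny, size
    xs = x0s[:, None] + off_x[None, :]          # nx, size
    patches = img[ys[:, None, :, None], xs[None, :, None, :]]  # ny,nx,size,size,3
    boxes = [
        BoundingBox(int(x0), int(y0), int(x0) + w, int(y0) + h)
        for y0 in y0s for x0 in x0s
    ]
    return patches.reshape(-1, size, size, img.shape[2]), boxes


def nms(detections: list[Detection], sq_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression: drop any box whose sq with an
    already-kept higher-scoring box exceeds ``sq_threshold``.

    Score ties break toward the larger box: a window covering the whole
    object then suppresses equally confident windows covering only part of
    it (a part box nested in a kept box always has sq > 1/2 with it).
    """
    kept: list[Detection] = []
    for det in sorted(detections, key=lambda d: (-d.score, -d.bbox.area)):
        if all(sq_score(det.bbox, k.bbox).sq <= sq_threshold for k in kept):
            kept.append(det)
    return kept


def _vote_refine(kept: list[Detection], pool: list[Detection]) -> list[Detection]:
    """Refine each kept box by score-weighted averaging of agreeing proposals."""
    refined = []
    for det in kept:
        corners = []
        weights = []
        for cand in pool:
            s = sq_score(cand.bbox, det.bbox).sq
            if s >= 0.55:
                corners.append([cand.bbox.x_min, cand.bbox.y_min,
                                cand.bbox.x_max, cand.bbox.y_max])
                weights.append(cand.score * s)
        if len(corners) > 1:
            c = np.average(np.array(corners, float), axis=0, weights=weights)
            box = BoundingBox(int(round(c[0])), int(round(c[1])),
                              max(int(round(c[2])), int(round(c[0])) + 1),
                              max(int(round(c[3])), int(round(c[1])) + 1))
            refined.append(Detection(bbox=box, score=det.score))
        else:
            refined.append(det)
    return refined


def _score_boxes(net, img: np.ndarray, boxes: list[BoundingBox],
                 patch_size: int) -> np.ndarray:
    patches = np.stack([_crop_resize(img, b, patch_size) for b in boxes])
    proba = net.predict_proba(_normalize(patches), batch_size=512)
    return proba[:, 1]


def _refine_boxes(seed: BoundingBox, scales, offsets,
                  tw: int, th: int) -> list[BoundingBox]:
    out = []
    cx = (seed.x_min + seed.x_max) / 2
    cy = (seed.y_min + seed.y_max) / 2
    # per-axis scale pairs: isotropic rescaling plus aspect adjustment
    for fw in scales:
        for fh in scales:
            w = max(int(round(seed.width * fw)), 8)
            h = max(int(round(seed.height * fh)), 8)
            for ox in offsets:
                for oy in offsets:
                    x0 = int(round(cx + ox * seed.width - w / 2))
                    y0 = int(round(cy + oy * seed.height - h / 2))
                    out.append(BoundingBox(x0, y0, x0 + w, y0 + h).clipped(tw, th))
    return out


def detect(model: DetectorModel, image: np.ndarray) -> list[Detection]:
    """Run the detector on one RGB image.

    A coarse multi-scale sliding-window pass proposes seed regions; a dense
    local grid around each surviving seed refines location and scale.  The
    final detections are score-thresholded, suppressed at
    ``config.nms_sq_threshold`` and returned sorted by descending score in
    standardized-frame coordinates.
    """
    if not model.trained:
        raise RuntimeError("detector model is untrained")
    config = model.config
    img, _scales = resize_for_detection(image, config.input_size)
    th, tw = config.input_size

    # stage 1: coarse objectness sweep with the proposal network
    coarse: list[Detection] = []
    for w, h, x0s, y0s in _proposal_grid(config):
        patches, boxes = _gather_patches(img, w, h, x0s, y0s, config.patch_size)
        proba = model.proposal_net.predict_proba(_normalize(patches),
                                                 batch_size=512)
        coarse.extend(Detection(bbox=b, score=float(s))
                      for b, s in zip(boxes, proba[:, 1])
                      if s >= config.seed_score_threshold)
    seeds = nms(coarse, 0.25)[: config.max_seeds]

    # stage 2: iterative local refinement scored by the detection network;
    # each round sweeps an offset/scale grid around the current best box
    pool: list[Detection] = []
    for seed in seeds:
        best = seed
        for rnd in range(config.refine_rounds):
            if rnd == 0:
                scales, offsets = (config.refine_wide_scales,
                                   config.refine_wide_offsets)
            else:
                scales, offsets = (config.refine_narrow_scales,
                                   config.refine_narrow_offsets)
            boxes = _refine_boxes(best.bbox, scales, offsets, tw, th)
            scores = _score_boxes(model.detection_net, img, boxes,
                                  config.patch_size)
            round_dets = [Detection(bbox=b, score=float(s))
                          for b, s in zip(boxes, scores)
                          if s >= 0.1]
            pool.extend(round_dets)
            if round_dets:
                # prefer the largest box among the top scorers so partial
                # windows do not shrink the final extent
                top = max(d.score for d in round_dets)
                best = max((d for d in round_dets if d.score >= 0.98 * top),
                           key=lambda d: d.bbox.area)

    candidates = [d for d in pool
                  if d.score >= config.score_threshold
                  and d.bbox.width >= config.min_detection_size
                  and d.bbox.height >= config.min_detection_size]
    kept = nms(candidates, config.nms_sq_threshold)
    kept = _vote_refine(kept, pool)
    # refinement moves boxes, so suppress again for an idempotent output
    kept = nms(kept, config.nms_sq_threshold)
    kept = [Detection(bbox=d.bbox.clipped(tw, th), score=d.score) for d in kept]
    return sorted(kept, key=lambda d: -d.score)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: DetectorModel, path: str | Path) -> None:
    """Persist config + weights to a single ``.npz`` file."""
    if not model.trained:
        raise RuntimeError("refusing to save an untrained model")
    arrays = {}
    for prefix, net in (("prop", model.proposal_net),
                        ("det", model.detection_net)):
        for key, value in net.state_arrays().items():
            arrays[f"{prefix}_{key}"] = value
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **arrays)


def load_model(path: str | Path) -> DetectorModel:
    with np.load(Path(path)) as data:
        cfg_raw = json.loads(bytes(data["config_json"].tobytes()).decode())

        def untuple(v):
            return tuple(untuple(x) for x in v) if isinstance(v, list) else v

        config = DetectorConfig(**{k: untuple(v) for k, v in cfg_raw.items()})
        nets = {}
        for prefix in ("prop", "det"):
            net = _build_net(config, np.random.default_rng(0))
            net.load_state_arrays({
                k[len(prefix) + 1:]: v for k, v in data.items()
                if k.startswith(prefix + "_")
            })
            nets[prefix] = net
    return DetectorModel(config, nets["prop"], nets["det"])
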