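"""Synthetic post-harvest stump scenes with exact ground truth.

Real harvest-site photo sets of cut Norway-spruce stumps with pixelwise rot
annotation are rarely redistributable, so this module renders labeled scenes
that emulate their statistical structure: a single (by default) stump disc —
concentric growth-ring texture, a darker bark annulus, an optional darker and
noisier rot region — lying on a cluttered forest-floor background of needles,
branches and sawdust, photographed at varying apparent distance (disc radius),
lighting and occlusion.

Ground truth is exact by construction: the stump and rot masks are captured
*before* lighting, shading and shadow are applied, mirroring the fact that a
human annotator outlines the physical stump surface regardless of
illumination.  The rot-area ratio (RBR ratio) is a pixel-count ratio
``|rot| / |stump|`` and drives a three-way severity grade used in timber
bucking: no rot at all, rot below half the surface, rot covering half or
more.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage import draw as skdraw
from skimage.transform import resize

from .segquality import BoundingBox

__all__ = [
    "RotClass",
    "SceneParams",
    "StumpAnnotation",
    "LabeledScene",
    "class_from_ratio",
    "rbr_ratio",
    "render_scene",
    "generate_dataset",
    "load_dataset",
    "default_class_mix",
    "REFERENCE_CLASS_COUNTS",
]

#: Class mix of the reference field campaign this generator emulates:
#: 502 stumps without rot, 197 with rot below 50%, 301 with rot >= 50%.
REFERENCE_CLASS_COUNTS = (502, 197, 301)


class RotClass(enum.IntEnum):
    """Rot-severity grade; ordering reflects increasing severity."""

    NO_ROT = 0
    ROT_LT_50 = 1
    ROT_GE_50 = 2


def class_from_ratio(r: float) -> RotClass:
    """Severity grade from the pixelwise rot-area ratio.

    ``r = 0`` maps to NO_ROT, ``0 < r < 0.5`` to ROT_LT_50 and ``r >= 0.5``
    to ROT_GE_50 — the grade boundaries used when bucking logs (saw timber
    tolerates no rot; prime pulpwood up to half).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"rot ratio must be in [0, 1], got {r}")
    if r == 0.0:
        return RotClass.NO_ROT
    if r < 0.5:
        return RotClass.ROT_LT_50
    return RotClass.ROT_GE_50


def rbr_ratio(rot_mask: np.ndarray, stump_mask: np.ndarray) -> float:
    """Pixel-count rot-area ratio ``|rot| / |stump|``.

    Raises on an empty stump mask or on rot pixels outside the stump.
    """
    rot = np.asarray(rot_mask, dtype=bool)
    stump = np.asarray(stump_mask, dtype=bool)
    n_stump = int(stump.sum())
    if n_stump == 0:
        raise ValueError("stump mask is empty")
    if np.any(rot & ~stump):
        raise ValueError("rot mask extends outside the stump mask")
    return int(rot.sum()) / n_stump


@dataclass(frozen=True)
class SceneParams:
    """Rendering conditions for one scene.

    ``stump_radius_range`` is a fraction of the shorter image side and stands
    in for camera-to-stump distance; ``occlusion_fraction`` is the fraction of
    stump-surface pixels covered by clutter drawn over the disc;
    ``lighting_gain`` is the range of a global multiplicative brightness
    jitter.  Identical params (including ``seed``) render bit-identical
    scenes.
    """

    image_height: int = 300
    image_width: int = 400
    stump_radius_range: tuple[float, float] = (0.08, 0.35)
    target_rbr_ratio: float = 0.0
    occlusion_fraction: float = 0.0
    lighting_gain: tuple[float, float] = (1.0, 1.0)
    shadow: bool = False
    n_stumps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stump_radius_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"stump_radius_range must lie in (0, 0.5]: {self.stump_radius_range}")
        if not 0.0 <= self.target_rbr_ratio <= 1.0:
            raise ValueError(f"target_rbr_ratio must be in [0, 1]: {self.target_rbr_ratio}")
        if not 0.0 <= self.occlusion_fraction <= 0.4:
            raise ValueError(f"occlusion_fraction must be in [0, 0.4]: {self.occlusion_fraction}")
        glo, ghi = self.lighting_gain
        if not (0.0 < glo <= ghi):
            raise ValueError(f"lighting_gain range invalid: {self.lighting_gain}")
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image must be at least 32x32")
        if self.n_stumps < 1:
            raise ValueError("n_stumps must be >= 1")


@dataclass(frozen=True)
class StumpAnnotation:
    """Ground truth for one stump in a scene."""

    stump_mask: np.ndarray
    rot_mask: np.ndarray
    bbox: BoundingBox
    rbr_ratio: float
    rot_class: RotClass


@dataclass(frozen=True)
class LabeledScene:
    """Rendered image plus exact per-stump ground truth.

    Single-stump scenes are the default; the singular accessors expose the
    first (usually only) stump.
    """

    image: np.ndarray  # H x W x 3 uint8
    annotations: tuple[StumpAnnotation, ...]
    params: SceneParams | None = None

    @property
    def stump_mask(self) -> np.ndarray:
        return self.annotations[0].stump_mask

    @property
    def rot_mask(self) -> np.ndarray:
        return self.annotations[0].rot_mask

    @property
    def bbox(self) -> BoundingBox:
        return self.annotations[0].bbox

    @property
    def rbr_ratio(self) -> float:
        return self.annotations[0].rbr_ratio

    @property
    def rot_class(self) -> RotClass:
        return self.annotations[0].rot_class


# ---------------------------------------------------------------------------
# rendering internals
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], cells: int = 8) -> np.ndarray:
    """Band-limited noise in [-1, 1]: a coarse random grid upsampled smoothly."""
    coarse = rng.uniform(-1.0, 1.0, size=(cells, cells))
    return resize(coarse, shape, order=3, mode="reflect", anti_aliasing=False)


def _draw_background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    img = np.empty((h, w, 3), dtype=np.float64)
    base = np.array([72.0, 62.0, 44.0])  # dark humus brown
    tint = _smooth_noise(rng, (h, w), cells=6)
    for c, scale in enumerate((28.0, 30.0, 18.0)):
        img[..., c] = base[c] + scale * tint + rng.normal(0.0, 7.0, size=(h, w))
    # moss/ground-vegetation patches
    green = _smooth_noise(rng, (h, w), cells=5)
    gm = green > 0.45
    img[gm] = img[gm] * 0.6 + np.array([40.0, 95.0, 35.0]) * 0.4

    # needles: short thin orange-brown strokes
    for _ in range(rng.integers(90, 150)):
        y0, x0 = rng.integers(0, h), rng.integers(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(8, 35)
        y1 = int(np.clip(y0 + length * np.sin(ang), 0, h - 1))
        x1 = int(np.clip(x0 + length * np.cos(ang), 0, w - 1))
        rr, cc = skdraw.line(y0, x0, y1, x1)
        color = np.array([150, 95, 45]) + rng.normal(0, 12, size=3)
        img[rr, cc] = color
    # branches: thicker dark strokes
    for _ in range(rng.integers(4, 9)):
        y0, x0 = rng.integers(0, h), rng.integers(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(40, 140)
        thick = rng.uniform(2, 5)
        _stroke(img, y0, x0, ang, length, thick, np.array([70, 50, 32]) + rng.normal(0, 8, 3))
    # sawdust: small pale blobs
    for _ in range(rng.integers(15, 40)):
        y0, x0 = rng.integers(0, h), rng.integers(0, w)
        r = rng.uniform(1.5, 5)
        rr, cc = skdraw.disk((y0, x0), r, shape=(h, w))
        img[rr, cc] = np.array([205, 185, 140]) + rng.normal(0, 10, size=3)
    return img


def _stroke(img, y0, x0, ang, length, thickness, color) -> np.ndarray:
    """Draw a thick line segment; returns the painted-pixel mask."""
    h, w = img.shape[:2]
    dy, dx = np.sin(ang), np.cos(ang)
    ny, nx = -dx, dy  # unit normal
    t = thickness / 2.0
    ys = [y0 - ny * t, y0 + ny * t, y0 + dy * length + ny * t, y0 + dy * length - ny * t]
    xs = [x0 - nx * t, x0 + nx * t, x0 + dx * length + nx * t, x0 + dx * length - nx * t]
    rr, cc = skdraw.polygon(ys, xs, shape=(h, w))
    img[rr, cc] = color
    painted = np.zeros((h, w), dtype=bool)
    painted[rr, cc] = True
    return painted


def _elliptical_coords(h, w, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    return rho, phi


def _rot_pixel_count(target: float, n_stump: int, rot_class_hint: RotClass | None) -> int:
    """Number of rot pixels that realizes the target ratio.

    When a class is requested, the count is clamped so the realized grade can
    never cross the 50% boundary through rounding.
    """
    k = int(round(target * n_stump))
    if target > 0:
        k = max(k, 1)
    half = int(np.ceil(0.5 * n_stump))
    if rot_class_hint is RotClass.ROT_LT_50:
        k = min(max(k, 1), half - 1)
    elif rot_class_hint is RotClass.ROT_GE_50:
        k = max(k, half)
    return min(k, n_stump)


def _render_stump(img, rng, params: SceneParams, center, radius_px, target,
                  rot_class_hint) -> StumpAnnotation:
    h, w = img.shape[:2]
    cy, cx = center
    a = radius_px
    b = radius_px * rng.uniform(0.72, 0.98)  # viewing-angle foreshortening
    theta = rng.uniform(0, np.pi)
    rho, phi = _elliptical_coords(h, w, cy, cx, a, b, theta)
    stump_mask = rho <= 1.0
    n_stump = int(stump_mask.sum())
    if n_stump == 0:
        raise ValueError("stump fell entirely outside the frame")
    if target > 0 and n_stump == 0:
        raise ValueError("cannot place rot on a zero-area stump")

    # cut-surface wood with concentric growth rings
    n_rings = rng.uniform(6, 14)
    ring_phase = rng.uniform(0, 2 * np.pi)
    ring = 1.0 + 0.10 * np.sin(2 * np.pi * rho * n_rings + ring_phase)
    wood = np.array([208.0, 186.0, 148.0])
    grain = rng.normal(0.0, 6.0, size=(h, w))
    for c in range(3):
        img[..., c][stump_mask] = (wood[c] * ring + grain)[stump_mask]
    # radial crack lines
    for _ in range(rng.integers(2, 6)):
        ang = rng.uniform(0, 2 * np.pi)
        sel = stump_mask & (np.abs(np.angle(np.exp(1j * (phi - ang)))) < 0.02) & (rho > 0.15)
        img[sel] = np.array([120, 100, 70])
    # bark annulus
    bark = stump_mask & (rho > 0.86)
    img[bark] = np.array([88.0, 66.0, 46.0]) + rng.normal(0, 9, size=(h, w, 3))[bark]

    # rot region: threshold a smooth center-weighted, angularly lobed field so
    # the top-k stump pixels form a connected dark blob/sector hitting the
    # requested area exactly (to one pixel)
    rot_mask = np.zeros((h, w), dtype=bool)
    k = _rot_pixel_count(target, n_stump, rot_class_hint) if target > 0 else 0
    if rot_class_hint is RotClass.ROT_LT_50 and k == 0:
        k = 1
    if k > 0:
        lobe_ang = rng.uniform(0, 2 * np.pi)
        fld = (
            1.1 * (1.0 - rho)
            + 0.5 * np.cos(phi - lobe_ang)
            + 0.55 * _smooth_noise(rng, (h, w), cells=5)
        )
        vals = fld[stump_mask]
        order = np.argsort(vals)[::-1]
        sel = np.zeros(n_stump, dtype=bool)
        sel[order[:k]] = True
        rot_mask[stump_mask] = sel
        rot_color = np.array([118.0, 96.0, 72.0])
        rot_noise = rng.normal(0.0, 16.0, size=(h, w))
        shade = 1.0 + 0.12 * _smooth_noise(rng, (h, w), cells=7)
        for c in range(3):
            img[..., c][rot_mask] = (rot_color[c] * shade + rot_noise)[rot_mask]

    ratio = int(rot_mask.sum()) / n_stump
    return StumpAnnotation(
        stump_mask=stump_mask,
        rot_mask=rot_mask,
        bbox=BoundingBox.from_mask(stump_mask),
        rbr_ratio=ratio,
        rot_class=class_from_ratio(ratio),
    )


def _occlude(img, rng, stump_mask, fraction) -> None:
    """Cover roughly ``fraction`` of the stump surface with clutter strokes."""
    if fraction <= 0:
        return
    n_stump = int(stump_mask.sum())
    target_px = fraction * n_stump
    ys, xs = np.nonzero(stump_mask)
    covered = np.zeros_like(stump_mask)
    for _ in range(200):
        if covered.sum() >= target_px:
            break
        i = rng.integers(0, len(ys))
        y0, x0 = int(ys[i]), int(xs[i])
        ang = rng.uniform(0, 2 * np.pi)
        if rng.random() < 0.6:  # needle bundle
            color = np.array([150, 95, 45]) + rng.normal(0, 12, 3)
            painted = _stroke(img, y0, x0, ang, rng.uniform(15, 60), rng.uniform(1, 3), color)
        else:  # branch
            color = np.array([70, 50, 32]) + rng.normal(0, 8, 3)
            painted = _stroke(img, y0, x0, ang, rng.uniform(30, 90), rng.uniform(3, 6), color)
        covered |= painted & stump_mask


def _apply_lighting(img, rng, params: SceneParams) -> None:
    h, w = img.shape[:2]
    gain = rng.uniform(*params.lighting_gain)
    # linear illumination gradient across a random direction
    ang = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (xx * np.cos(ang) + yy * np.sin(ang)) / np.hypot(h, w)
    ramp = 1.0 + 0.25 * (ramp - ramp.mean()) * rng.uniform(0, 1)
    img *= gain * ramp[..., None]
    if params.shadow and rng.random() < 0.5:
        sy, sx = rng.integers(0, h), rng.integers(0, w)
        rr, cc = skdraw.ellipse(
            sy, sx, rng.uniform(0.3, 0.8) * h, rng.uniform(0.3, 0.8) * w, shape=(h, w),
            rotation=rng.uniform(0, np.pi),
        )
        img[rr, cc] *= 0.62


def render_scene(params: SceneParams) -> LabeledScene:
    """Render one labeled scene deterministically from ``params``.

    The realized RBR ratio is within +/-0.02 of ``params.target_rbr_ratio``
    (in practice within one pixel of the exact count), and masks/boxes are
    exact because photometric effects are applied after ground-truth capture.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    img = _draw_background(rng, h, w)

    annotations = []
    occupied = np.zeros((h, w), dtype=bool)
    for _ in range(params.n_stumps):
        for _attempt in range(50):
            frac = rng.uniform(*params.stump_radius_range)
            radius = frac * min(h, w)
            margin = radius + 2
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            trial_rho, _ = _elliptical_coords(h, w, cy, cx, radius, radius, 0.0)
            if not (occupied & (trial_rho <= 1.2)).any():
                break
        ann = _render_stump(img, rng, params, (cy, cx), radius,
                            params.target_rbr_ratio, None)
        occupied |= ann.stump_mask
        annotations.append(ann)

    for ann in annotations:
        _occlude(img, rng, ann.stump_mask, params.occlusion_fraction)
    _apply_lighting(img, rng, params)
    image = np.clip(img, 0, 255).astype(np.uint8)
    scene = LabeledScene(image=image, annotations=tuple(annotations), params=params)
    if abs(scene.rbr_ratio - params.target_rbr_ratio) > 0.02:
        raise ValueError(
            f"target RBR ratio {params.target_rbr_ratio} unreachable "
            f"(realized {scene.rbr_ratio:.3f})"
        )
    return scene


def _render_for_class(params: SceneParams, rot_class: RotClass, target: float) -> LabeledScene:
    """Render with a class-clamped rot pixel count (dataset generation path)."""
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    img = _draw_background(rng, h, w)
    frac = rng.uniform(*params.stump_radius_range)
    radius = frac * min(h, w)
    margin = radius + 2
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    ann = _render_stump(img, rng, params, (cy, cx), radius, target, rot_class)
    _occlude(img, rng, ann.stump_mask, params.occlusion_fraction)
    _apply_lighting(img, rng, params)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return LabeledScene(image=image, annotations=(ann,), params=params)


# ---------------------------------------------------------------------------
# dataset generation and I/O
# ---------------------------------------------------------------------------


def default_class_mix(n_total: int) -> tuple[int, int, int]:
    """Split ``n_total`` proportionally to the reference 502/197/301 mix."""
    total_ref = sum(REFERENCE_CLASS_COUNTS)
    raw = [n_total * c / total_ref for c in REFERENCE_CLASS_COUNTS]
    counts = [int(np.floor(v)) for v in raw]
    # distribute the remainder by largest fractional part
    rem = n_total - sum(counts)
    frac_order = np.argsort([v - np.floor(v) for v in raw])[::-1]
    for i in range(rem):
        counts[frac_order[i]] += 1
    return tuple(counts)


_CLASS_TARGET_RANGES = {
    RotClass.NO_ROT: (0.0, 0.0),
    RotClass.ROT_LT_50: (0.05, 0.45),
    RotClass.ROT_GE_50: (0.52, 0.95),
}


def generate_scenes(
    n_per_class: tuple[int, int, int],
    params_template: SceneParams = SceneParams(),
    seed: int = 0,
    occlusion_is_max: bool = True,
) -> list[LabeledScene]:
    """Render ``sum(n_per_class)`` scenes with exact class counts, in memory.

    Per-scene seeds and rot targets derive deterministically from ``seed``.
    With ``occlusion_is_max`` the template's occlusion fraction is the upper
    end of a per-scene uniform draw, emulating "varied degree of occlusion".
    """
    master = np.random.default_rng(seed)
    scene_seeds = master.integers(0, 2**31 - 1, size=sum(n_per_class))
    scenes: list[LabeledScene] = []
    i = 0
    for cls, n in zip(RotClass, n_per_class):
        lo, hi = _CLASS_TARGET_RANGES[cls]
        for _ in range(n):
            target = float(master.uniform(lo, hi)) if hi > lo else lo
            occ = params_template.occlusion_fraction
            if occlusion_is_max and occ > 0:
                occ = float(master.uniform(0.0, occ))
            p = replace(
                params_template,
                target_rbr_ratio=target,
                occlusion_fraction=occ,
                seed=int(scene_seeds[i]),
            )
            scenes.append(_render_for_class(p, cls, target))
            i += 1
    return scenes


def generate_dataset(
    n_per_class: tuple[int, int, int],
    out_dir: str | Path,
    params_template: SceneParams = SceneParams(),
    seed: int = 0,
) -> Path:
    """Render a dataset to ``out_dir`` and return the annotation index path.

    Layout: ``images/*.png`` (8-bit RGB), ``masks/*_stump.png`` and
    ``masks/*_rot.png`` (0/255), ``annotations.json`` (COCO-style with extra
    ``rbr_ratio`` and mask-path fields) and a flat ``annotations.csv``.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    scenes = generate_scenes(n_per_class, params_template, seed)

    images_meta, annotations_meta, csv_rows = [], [], []
    for idx, scene in enumerate(scenes):
        stem = f"scene_{idx:05d}"
        iio.imwrite(out / "images" / f"{stem}.png", scene.image)
        for ai, ann in enumerate(scene.annotations):
            suffix = "" if len(scene.annotations) == 1 else f"_{ai}"
            iio.imwrite(
                out / "masks" / f"{stem}{suffix}_stump.png",
                (ann.stump_mask.astype(np.uint8) * 255),
            )
            iio.imwrite(
                out / "masks" / f"{stem}{suffix}_rot.png",
                (ann.rot_mask.astype(np.uint8) * 255),
            )
        images_meta.append(
            {
                "id": idx,
                "file_name": f"images/{stem}.png",
                "height": scene.image.shape[0],
                "width": scene.image.shape[1],
            }
        )
        for ai, ann in enumerate(scene.annotations):
            suffix = "" if len(scene.annotations) == 1 else f"_{ai}"
            annotations_meta.append(
                {
                    "id": len(annotations_meta),
                    "image_id": idx,
                    "category_id": int(ann.rot_class),
                    "bbox": ann.bbox.as_xywh(),
                    "area": ann.bbox.area,
                    "rbr_ratio": ann.rbr_ratio,
                    "stump_mask": f"masks/{stem}{suffix}_stump.png",
                    "rot_mask": f"masks/{stem}{suffix}_rot.png",
                }
            )
            csv_rows.append(
                [f"images/{stem}.png", ann.rot_class.name, f"{ann.rbr_ratio:.6f}",
                 " ".join(map(str, ann.bbox.as_xywh()))]
            )

    index = {
        "images": images_meta,
        "annotations": annotations_meta,
        "categories": [
            {"id": int(c), "name": c.name} for c in RotClass
        ],
        "seed": seed,
        "n_per_class": list(n_per_class),
    }
    index_path = out / "annotations.json"
    index_path.write_text(json.dumps(index, indent=1, sort_keys=True))
    with open(out / "annotations.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "class", "rbr_ratio", "bbox_xywh"])
        writer.writerows(csv_rows)
    return index_path


def load_dataset(index_path: str | Path) -> list[LabeledScene]:
    """Load a generated dataset back into :class:`LabeledScene` objects."""
    import imageio.v3 as iio

    index_path = Path(index_path)
    root = index_path.parent
    index = json.loads(index_path.read_text())
    by_image: dict[int, list[dict]] = {}
    for ann in index["annotations"]:
        by_image.setdefault(ann["image_id"], []).append(ann)
    scenes = []
    for im in sorted(index["images"], key=lambda m: m["id"]):
        image = iio.imread(root / im["file_name"])
        anns = []
        for ann in by_image.get(im["id"], []):
            stump = iio.imread(root / ann["stump_mask"]) > 127
            rot = iio.imread(root / ann["rot_mask"]) > 127
            anns.append(
                StumpAnnotation(
                    stump_mask=stump,
                    rot_mask=rot,
                    bbox=BoundingBox.from_xywh(ann["bbox"]),
                    rbr_ratio=float(ann["rbr_ratio"]),
                    rot_class=RotClass(ann["category_id"]),
                )
            )
        scenes.append(LabeledScene(image=image, annotations=tuple(anns)))
    return scenes
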