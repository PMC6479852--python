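"""Segmentation-quality (sq) metric on bounding boxes and masks.

The detector is judged not by intersection-over-union but by *segmentation
quality*, the average of two ratios computed from the overlap area ``O``
between a segmented region ``S`` and a manually labeled region ``L``:

* segmentation-overlap ``O / L`` — what fraction of the labeled object was
  actually segmented;
* segmentation-efficiency ``O / S`` — what fraction of the segmented region
  covers the object rather than background.

``sq = (O/L + O/S) / 2`` lies in [0, 1] and equals 1 exactly when the two
regions coincide.  sq is deliberately *not* IoU and must not be silently
substituted by it: two regions with IoU 1/3 (half-overlapping equal-area
boxes) have sq 1/2.

Boxes are axis-aligned, 0-based, half-open ``[x_min, x_max) x [y_min, y_max)``
so areas and intersections are exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoundingBox", "SQResult", "intersect_area", "sq_score"]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, half-open in both axes."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def scaled(self, sx: float, sy: float) -> "BoundingBox":
        """Map the box through per-axis scale factors (x by sx, y by sy)."""
        return BoundingBox(
            x_min=int(round(self.x_min * sx)),
            y_min=int(round(self.y_min * sy)),
            x_max=max(int(round(self.x_max * sx)), int(round(self.x_min * sx)) + 1),
            y_max=max(int(round(self.y_max * sy)), int(round(self.y_min * sy)) + 1),
        )

    def clipped(self, width: int, height: int) -> "BoundingBox":
        """Clip to an image of the given size (raises if nothing remains)."""
        return BoundingBox(
            x_min=max(self.x_min, 0),
            y_min=max(self.y_min, 0),
            x_max=min(self.x_max, width),
            y_max=min(self.y_max, height),
        )

    def as_xywh(self) -> list[int]:
        return [self.x_min, self.y_min, self.width, self.height]

    @classmethod
    def from_xywh(cls, xywh) -> "BoundingBox":
        x, y, w, h = (int(v) for v in xywh)
        return cls(x, y, x + w, y + h)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "BoundingBox":
        """Tight bounding rectangle of a non-empty binary mask."""
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            raise ValueError("cannot bound an empty mask")
        return cls(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


@dataclass(frozen=True)
class SQResult:
    """O, L, S areas and the derived overlap / efficiency / sq fractions."""

    overlap_area: int
    labeled_area: int
    segmented_area: int

    @property
    def segmentation_overlap(self) -> float:
        return self.overlap_area / self.labeled_area

    @property
    def segmentation_efficiency(self) -> float:
        return self.overlap_area / self.segmented_area

    @property
    def sq(self) -> float:
        return 0.5 * (self.segmentation_overlap + self.segmentation_efficiency)


def intersect_area(a: BoundingBox, b: BoundingBox) -> int:
    """Area of the geometric intersection of two half-open boxes (0 if disjoint)."""
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0 or h <= 0:
        return 0
    return w * h


def _region_area_and_overlap(segmented, labeled) -> tuple[int, int, int]:
    seg_is_box = isinstance(segmented, BoundingBox)
    lab_is_box = isinstance(labeled, BoundingBox)
    if seg_is_box and lab_is_box:
        return intersect_area(segmented, labeled), labeled.area, segmented.area
    # at least one mask: rasterize boxes into the mask frame
    def to_mask(region, like: np.ndarray) -> np.ndarray:
        if isinstance(region, BoundingBox):
            m = np.zeros(like.shape, dtype=bool)
            m[region.y_min : region.y_max, region.x_min : region.x_max] = True
            return m
        return np.asarray(region, dtype=bool)

    ref = np.asarray(labeled if not lab_is_box else segmented)
    seg_m = to_mask(segmented, ref)
    lab_m = to_mask(labeled, ref)
    if seg_m.shape != lab_m.shape:
        raise ValueError("mask shapes differ")
    return int((seg_m & lab_m).sum()), int(lab_m.sum()), int(seg_m.sum())


def sq_score(segmented, labeled) -> SQResult:
    """Segmentation quality of a segmented region against a labeled region.

    Both arguments may be a :class:`BoundingBox` or a binary mask; areas are
    pixel counts in either representation.  Raises ``ValueError`` on an empty
    region.
    """
    overlap, lab_area, seg_area = _region_area_and_overlap(segmented, labeled)
    if lab_area == 0 or seg_area == 0:
        raise ValueError("sq is undefined for an empty region")
    return SQResult(overlap_area=overlap, labeled_area=lab_area, segmented_area=seg_area)
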