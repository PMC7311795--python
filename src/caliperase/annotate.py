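"""Caliper-marker simulation: glyphs, tangency placement, pseudo groups, mixup.

Clinicians burn bright caliper glyphs into the frame at the points where the
nodule contour touches its tight enclosing rectangle, in groups of two
(left/right) or four (one per side), each at a random position along its
side. Two decorrelation preprocesses are provided:

* pseudo groups — caliper groups with the same geometry dropped on
  nodule-free regions, so markers stop predicting nodules;
* mixup — part of each real group is kept, the rest erased by inpainting,
  and an equal number of replacement glyphs burned at random positions away
  from every nodule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from caliperase.phantom import Nodule, PlacementError

logger = logging.getLogger(__name__)

Rect = tuple[int, int, int, int]
Point = tuple[int, int]


class ContractError(ValueError):
    """An operation was called outside its contract."""


@dataclass(frozen=True)
class MarkerGlyph:
    """A caliper glyph burned into the image.

    shape : "plus" (axis-aligned cross) or "cross" (diagonal X).
    arm_length : half-extent of each arm, px (>= 2).
    thickness : line thickness, px.
    intensity : burned-in intensity in [0, 1]; calipers are bright.
    """

    shape: str = "plus"
    arm_length: int = 4
    thickness: int = 2
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("plus", "cross"):
            raise ValueError("shape must be 'plus' or 'cross'")
        if self.arm_length < 2:
            raise ValueError("arm_length must be >= 2")
        if not (0 <= self.intensity <= 1):
            raise ValueError("intensity must lie in [0, 1]")

    def offsets(self) -> np.ndarray:
        """(n, 2) array of (drow, dcol) footprint offsets around the center."""
        arm, t = self.arm_length, self.thickness
        half = (t - 1) // 2
        pts = set()
        for d in range(-arm, arm + 1):
            for w in range(-half, t - half):
                if self.shape == "plus":
                    pts.add((d, w))
                    pts.add((w, d))
                else:
                    pts.add((d, d + w))
                    pts.add((d, -d + w))
        return np.array(sorted(pts), dtype=int)

    def footprint_bbox(self, center: Point) -> Rect:
        off = self.offsets()
        r, c = center
        return (c + off[:, 1].min(), r + off[:, 0].min(),
                c + off[:, 1].max() + 1, r + off[:, 0].max() + 1)


@dataclass
class MarkerGroup:
    """A caliper group annotating (or mimicking) one nodule rectangle."""

    rect: Rect
    points: list[Point]
    group_size: int
    is_pseudo: bool = False

    def to_dict(self) -> dict:
        return {"rect": list(self.rect), "points": [list(p) for p in self.points],
                "group_size": self.group_size, "is_pseudo": self.is_pseudo}


@dataclass
class AnnotatedImage:
    """A phantom with glyphs burned in.

    ``mask`` has value True exactly where glyph pixels were written, so
    pixels outside the mask equal the pre-annotation image. ``loose_points``
    holds replacement markers added by mixup that are not tied to any
    group's rectangle.
    """

    image: np.ndarray
    groups: list[MarkerGroup]
    mask: np.ndarray
    nodules: list[Nodule] = field(default_factory=list)
    loose_points: list[Point] = field(default_factory=list)
    glyph: MarkerGlyph = field(default_factory=MarkerGlyph)
    original: np.ndarray | None = None


def tangency_points(rect: Rect, group_size: int, seed: int,
                    orientation: str = "lr") -> list[Point]:
    """Caliper centers on the sides of ``rect``.

    group_size 2 puts one point on the left and one on the right side
    (``orientation="tb"`` uses top/bottom instead); group_size 4 puts exactly
    one point on each of the four sides. Positions along each side are
    seeded-uniform.
    """
    if group_size not in (2, 4):
        raise ContractError(f"group_size must be 2 or 4, got {group_size}")
    x0, y0, x1, y1 = rect
    if x1 - x0 < 8 or y1 - y0 < 8:
        raise ContractError(f"rect {rect} smaller than 8x8")
    rng = np.random.default_rng(seed)

    def along_v() -> int:  # row on a vertical side
        return int(rng.integers(y0, y1))

    def along_h() -> int:  # col on a horizontal side
        return int(rng.integers(x0, x1))

    left = (along_v(), x0)
    right = (along_v(), x1 - 1)
    if group_size == 2:
        if orientation == "tb":
            return [(y0, along_h()), (y1 - 1, along_h())]
        return [left, right]
    top = (y0, along_h())
    bottom = (y1 - 1, along_h())
    return [left, right, top, bottom]


def burn_glyphs(image: np.ndarray, points: list[Point], glyph: MarkerGlyph,
                mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Burn glyphs at ``points`` into a copy of ``image``; returns (image, mask).

    Footprints that stick out of the image are clipped (with a log warning),
    as happens for calipers near the frame border in practice.
    """
    h, w = image.shape
    out = image.copy()
    new_mask = np.zeros((h, w), dtype=bool) if mask is None else mask.copy()
    off = glyph.offsets()
    for (r, c) in points:
        rr = r + off[:, 0]
        cc = c + off[:, 1]
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        if not inside.all():
            logger.warning("glyph at (%d, %d) clipped at image border", r, c)
        out[rr[inside], cc[inside]] = glyph.intensity
        new_mask[rr[inside], cc[inside]] = True
    return out, new_mask


def annotate_nodule(image: np.ndarray, nodule: Nodule,
                    glyph: MarkerGlyph | None = None, group_size: int = 2,
                    seed: int = 0) -> AnnotatedImage:
    """Burn a caliper group at the tangency points of the nodule's bbox."""
    if glyph is None:
        glyph = MarkerGlyph()
    h, w = image.shape
    x0, y0, x1, y1 = nodule.bbox
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise PlacementError(f"nodule bbox {nodule.bbox} outside {h}x{w} image")
    points = tangency_points(nodule.bbox, group_size, seed)
    burned, mask = burn_glyphs(image, points, glyph)
    group = MarkerGroup(rect=nodule.bbox, points=points, group_size=group_size)
    return AnnotatedImage(image=burned, groups=[group], mask=mask,
                          nodules=[nodule], glyph=glyph, original=image.copy())


def annotate_phantom(image: np.ndarray, nodules: list[Nodule],
                     glyph: MarkerGlyph | None = None, seed: int = 0) -> AnnotatedImage:
    """Annotate every nodule of a phantom, group size seeded-uniform in {2, 4}."""
    if glyph is None:
        glyph = MarkerGlyph()
    rng = np.random.default_rng(seed)
    burned = image
    mask = np.zeros(image.shape, dtype=bool)
    groups = []
    for nod in nodules:
        gsize = int(rng.choice([2, 4]))
        pts = tangency_points(nod.bbox, gsize, seed=int(rng.integers(0, 2**31 - 1)))
        burned, mask = burn_glyphs(burned, pts, glyph, mask)
        groups.append(MarkerGroup(rect=nod.bbox, points=pts, group_size=gsize))
    return AnnotatedImage(image=burned, groups=groups, mask=mask,
                          nodules=list(nodules), glyph=glyph, original=image.copy())


def _rect_iou_zero(rect: Rect, boxes: list[Rect]) -> bool:
    x0, y0, x1, y1 = rect
    for (u0, v0, u1, v1) in boxes:
        if x0 < u1 and u0 < x1 and y0 < v1 and v0 < y1:
            return False
    return True


def generate_pseudo_group(image: np.ndarray, nodules: list[Nodule],
                          max_dims: tuple[int, int], seed: int,
                          group_size: int | None = None,
                          max_attempts: int = 200) -> MarkerGroup:
    """Sample a pseudo caliper group away from every real nodule.

    The group's rectangle (i) never exceeds ``max_dims = (w, h)``, the
    dimensions of the largest nodule box in the training set, and (ii) has
    IoU 0 with every real nodule box. Group size is drawn uniformly from
    {2, 4} unless forced. Rejection-sampled; raises :class:`PlacementError`
    after ``max_attempts`` failures.
    """
    h, w = image.shape
    max_w, max_h = max_dims
    max_w, max_h = min(max_w, w), min(max_h, h)
    if max_w < 8 or max_h < 8:
        raise PlacementError("max_dims too small for an 8x8 caliper rectangle")
    rng = np.random.default_rng(seed)
    boxes = [n.bbox for n in nodules]
    for _ in range(max_attempts):
        rw = int(rng.integers(8, max_w + 1))
        rh = int(rng.integers(8, max_h + 1))
        x0 = int(rng.integers(0, w - rw + 1))
        y0 = int(rng.integers(0, h - rh + 1))
        rect = (x0, y0, x0 + rw, y0 + rh)
        if not _rect_iou_zero(rect, boxes):
            continue
        gsize = group_size if group_size is not None else int(rng.choice([2, 4]))
        pts = tangency_points(rect, gsize, seed=int(rng.integers(0, 2**31 - 1)))
        return MarkerGroup(rect=rect, points=pts, group_size=gsize, is_pseudo=True)
    raise PlacementError(f"no pseudo-group placement found in {max_attempts} attempts")


def add_pseudo_groups(annotated: AnnotatedImage, max_dims: tuple[int, int],
                      n_groups: tuple[int, int] = (1, 2), seed: int = 0) -> AnnotatedImage:
    """Burn 1-2 (seeded) pseudo groups into an annotated image."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_groups[0], n_groups[1] + 1))
    burned, mask = annotated.image, annotated.mask
    groups = list(annotated.groups)
    for _ in range(n):
        grp = generate_pseudo_group(burned, annotated.nodules, max_dims,
                                    seed=int(rng.integers(0, 2**31 - 1)))
        burned, mask = burn_glyphs(burned, grp.points, annotated.glyph, mask)
        groups.append(grp)
    return AnnotatedImage(image=burned, groups=groups, mask=mask,
                          nodules=annotated.nodules, loose_points=list(annotated.loose_points),
                          glyph=annotated.glyph, original=annotated.original)


def _glyph_iou_zero(center: Point, glyph: MarkerGlyph, boxes: list[Rect]) -> bool:
    return _rect_iou_zero(glyph.footprint_bbox(center), boxes)


def mixup_markers(annotated: AnnotatedImage, seed: int,
                  max_attempts: int = 200) -> AnnotatedImage:
    """Destroy the spatial structure of real caliper groups.

    For every 2-marker group exactly one original point is kept; for every
    4-marker group a seeded-uniform 1-3 points are kept. Removed glyphs are
    erased by texture-synthesis inpainting, and one replacement glyph per
    removed glyph is burned at a seeded-random position whose footprint has
    IoU 0 with every nodule box.
    """
    from caliperase.inpaint import inpaint_texture  # local import: avoid cycle

    if not annotated.groups:
        raise ContractError("mixup requires at least one marker group")
    rng = np.random.default_rng(seed)
    glyph = annotated.glyph
    h, w = annotated.image.shape
    boxes = [n.bbox for n in annotated.nodules]

    kept_groups: list[MarkerGroup] = []
    removed_points: list[Point] = []
    n_replace = 0
    for grp in annotated.groups:
        pts = list(grp.points)
        if grp.group_size == 2:
            keep_n = 1
        else:
            keep_n = int(rng.integers(1, 4))  # 1..3
        keep_n = min(keep_n, len(pts))
        keep_idx = rng.choice(len(pts), size=keep_n, replace=False)
        keep_idx = sorted(int(i) for i in keep_idx)
        kept = [pts[i] for i in keep_idx]
        removed = [p for i, p in enumerate(pts) if i not in keep_idx]
        removed_points.extend(removed)
        n_replace += len(removed)
        kept_groups.append(MarkerGroup(rect=grp.rect, points=kept,
                                       group_size=grp.group_size, is_pseudo=grp.is_pseudo))

    # erase removed glyphs (their footprint minus pixels shared with kept glyphs)
    erase_mask = np.zeros((h, w), dtype=bool)
    _, erase_mask = burn_glyphs(np.zeros((h, w)), removed_points, glyph, erase_mask)
    keep_mask = np.zeros((h, w), dtype=bool)
    kept_pts = [p for g in kept_groups for p in g.points] + list(annotated.loose_points)
    _, keep_mask = burn_glyphs(np.zeros((h, w)), kept_pts, glyph, keep_mask)
    erase_mask &= ~keep_mask
    erase_mask = binary_dilation(erase_mask, iterations=1) & ~keep_mask

    if erase_mask.any():
        result = inpaint_texture(annotated.image, erase_mask,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        image = result.image
    else:
        image = annotated.image.copy()
    mask = keep_mask.copy()  # burned pixels that remain after the erase

    # burn replacements away from every nodule
    new_points: list[Point] = []
    arm = glyph.arm_length
    for _ in range(n_replace):
        for _ in range(max_attempts):
            r = int(rng.integers(arm, h - arm))
            c = int(rng.integers(arm, w - arm))
            if _glyph_iou_zero((r, c), glyph, boxes):
                new_points.append((r, c))
                break
        else:
            raise PlacementError("no valid position for a replacement marker")
    image, mask = burn_glyphs(image, new_points, glyph, mask)
    return AnnotatedImage(image=image, groups=kept_groups, mask=mask,
                          nodules=annotated.nodules,
                          loose_points=list(annotated.loose_points) + new_points,
                          glyph=glyph, original=annotated.original)


def marker_mask(groups: list[MarkerGroup], glyph: MarkerGlyph,
                shape: tuple[int, int], dilation: int = 0,
                loose_points: list[Point] | None = None) -> np.ndarray:
    """Union of glyph footprints, optionally dilated by ``dilation`` px."""
    if dilation < 0:
        raise ContractError("dilation must be >= 0")
    mask = np.zeros(shape, dtype=bool)
    points = [p for g in groups for p in g.points]
    if loose_points:
        points += list(loose_points)
    if points:
        _, mask = burn_glyphs(np.zeros(shape), points, glyph, mask)
    if dilation > 0 and mask.any():
        mask = binary_dilation(mask, iterations=dilation)
    return mask
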