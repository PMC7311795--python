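"""Desk-scale nodule detector: multi-scale sliding-window patch scoring + NMS.

A crop classifier (the baseline or VIB model from :mod:`caliperase.vib`)
scores square windows at two scales; windows above a score threshold go
through greedy non-maximum suppression. This deliberately simple detector is
enough to expose marker shortcut learning: if the classifier keys on caliper
glyphs, detection collapses on marker-free images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from caliperase import vib
from caliperase.evalx import iou
from caliperase.phantom import Nodule


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class Detection:
    """A scored half-open bounding box (x0, y0, x1, y1)."""

    bbox: tuple[float, float, float, float]
    score: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"bbox": [float(v) for v in self.bbox], "score": float(self.score)}


@dataclass
class DetectorConfig:
    windows: tuple[int, ...] = (24, 32, 40)
    stride: int = 5
    score_threshold: float = 0.5
    nms_iou: float = 0.15
    crop_margin: int = 6          # context around a gt box in harvested crops
    neg_ratio: float = 2.0        # negatives per positive
    classifier: vib.ClassifierConfig = field(
        default_factory=lambda: vib.ClassifierConfig(use_vib=False, epochs=30))

    def __post_init__(self) -> None:
        self.windows = tuple(sorted(self.windows))
        if not (0 < self.nms_iou < 1):
            raise ValueError("nms_iou must lie in (0, 1)")


@dataclass
class DetectorModel:
    classifier: vib.VIBModel
    config: DetectorConfig
    crop_manifest: list[dict] = field(default_factory=list)


_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _area_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic box-overlap averaging matrix."""
    key = (n_in, n_out)
    if key not in _RESIZE_CACHE:
        mat = np.zeros((n_out, n_in))
        scale = n_in / n_out
        for o in range(n_out):
            lo, hi = o * scale, (o + 1) * scale
            for i in range(int(np.floor(lo)), min(n_in, int(np.ceil(hi)))):
                mat[o, i] = min(hi, i + 1) - max(lo, i)
        mat /= mat.sum(axis=1, keepdims=True)
        _RESIZE_CACHE[key] = mat
    return _RESIZE_CACHE[key]


def resize_area(crops: np.ndarray, side: int) -> np.ndarray:
    """Exact area-average resize of (..., h, w) crops to (..., side, side).

    Area pooling keeps thin bright structures (1-px caliper arms) visible as
    proportionally dimmer lines instead of aliasing them away.
    """
    h, w = crops.shape[-2:]
    if (h, w) == (side, side):
        return crops.copy()
    left = _area_matrix(h, side)
    right = _area_matrix(w, side)
    return np.einsum("oh,...hw,pw->...op", left, crops, right, optimize=True)


def _square_crop_bounds(box, margin: int, shape: tuple[int, int]
                        ) -> tuple[int, int, int]:
    """(r0, c0, side) of a square context crop around a box, kept in-image."""
    x0, y0, x1, y1 = box
    side = int(max(x1 - x0, y1 - y0) + 2 * margin)
    h, w = shape
    side = min(side, h, w)
    r0 = int(np.clip(round((y0 + y1) / 2 - side / 2), 0, h - side))
    c0 = int(np.clip(round((x0 + x1) / 2 - side / 2), 0, w - side))
    return r0, c0, side


def harvest_crops(items: list[tuple[np.ndarray, list[Nodule]]],
                  config: DetectorConfig, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Positive crops from gt boxes, negatives from IoU-0 regions.

    Returns (crops, labels, manifest); crops are resized to the classifier
    input side. The negative:positive ratio follows the config (rounded).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE7]))
    side_out = config.classifier.input_side
    crops, labels, manifest = [], [], []
    for img_idx, (image, nodules) in enumerate(items):
        shape = image.shape
        boxes = [n.bbox for n in nodules]
        for nod in nodules:
            r0, c0, s = _square_crop_bounds(nod.bbox, config.crop_margin, shape)
            crop = image[r0:r0 + s, c0:c0 + s]
            crops.append(resize_area(crop, side_out))
            labels.append(1)
            manifest.append({"image": img_idx, "kind": "pos",
                             "window": [c0, r0, c0 + s, r0 + s]})
        n_neg = int(round(config.neg_ratio * len(nodules)))
        h, w = shape
        for _ in range(n_neg):
            for _attempt in range(100):
                s = int(rng.integers(config.windows[0], config.windows[-1] + 1))
                if s > min(h, w):
                    continue
                r0 = int(rng.integers(0, h - s + 1))
                c0 = int(rng.integers(0, w - s + 1))
                window = (c0, r0, c0 + s, r0 + s)
                if all(iou(window, b) == 0.0 for b in boxes):
                    crop = image[r0:r0 + s, c0:c0 + s]
                    crops.append(resize_area(crop, side_out))
                    labels.append(0)
                    manifest.append({"image": img_idx, "kind": "neg",
                                     "window": list(window)})
                    break
    if not any(labels):
        raise DataError("no positive crops harvested")
    return np.array(crops), np.array(labels), manifest


def train_detector(items: list[tuple[np.ndarray, list[Nodule]]],
                   config: DetectorConfig | None = None, seed: int = 0) -> DetectorModel:
    """Train the patch classifier on harvested crops (baseline or VIB)."""
    if config is None:
        config = DetectorConfig()
    crops, labels, manifest = harvest_crops(items, config, seed=seed)
    clf = vib.train_classifier(crops, labels, config.classifier, seed=seed)
    return DetectorModel(classifier=clf, config=config, crop_manifest=manifest)


def detect(image: np.ndarray, model: DetectorModel) -> list[Detection]:
    """Multi-scale sliding-window detection, thresholded then NMS'd.

    Deterministic given (image, model); detections are returned sorted by
    descending score.
    """
    cfg = model.config
    h, w = image.shape
    if min(h, w) < cfg.windows[0]:
        raise DataError("image smaller than the smallest window")
    cands: list[Detection] = []
    side_out = cfg.classifier.input_side
    for win in cfg.windows:
        if win > min(h, w):
            continue
        views = sliding_window_view(image, (win, win))[::cfg.stride, ::cfg.stride]
        nr, nc = views.shape[:2]
        batch = resize_area(views.reshape(nr * nc, win, win), side_out)
        probs = vib.predict(model.classifier, batch, mode="mean")[:, 1]
        keep = np.flatnonzero(probs >= cfg.score_threshold)
        m = min(cfg.crop_margin, (win - 2) // 2)
        for idx in keep:
            r = (idx // nc) * cfg.stride
            c = (idx % nc) * cfg.stride
            # windows score (object + context margin); the emitted box is the
            # central object region, matching the harvested-crop geometry
            cands.append(Detection(bbox=(c + m, r + m, c + win - m, r + win - m),
                                   score=float(probs[idx])))
    return nms(cands, cfg.nms_iou)


def nms(dets: list[Detection], iou_thresh: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-scored detection (ties by score, then
    smaller x0, then smaller y0) and discards every remaining detection with
    IoU >= ``iou_thresh`` against it.
    """
    pending = sorted(dets, key=lambda d: (-d.score, d.bbox[0], d.bbox[1]))
    kept: list[Detection] = []
    while pending:
        best = pending.pop(0)
        kept.append(best)
        pending = [d for d in pending if iou(d.bbox, best.bbox) < iou_thresh]
    return kept
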