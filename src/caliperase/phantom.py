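"""Synthetic ultrasound-like phantoms: speckle backgrounds and hypoechoic nodules.

Images are 2-D float arrays with intensities in [0, 1], 0-based (row, col)
indexing. Bounding boxes are half-open ``(x0, y0, x1, y1)`` with ``x`` = col
and ``y`` = row; this convention is shared by every module in the package.

The background model is fully developed speckle in its standard
approximation: a smooth low-frequency echogenicity field multiplied by
unit-mean gamma noise. The noise field is lightly smoothed ("grain") so that
speckle has a finite resolution-cell size, as in real B-mode images — this
spatial correlation is what makes exemplar-based inpainting meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

MIN_IMAGE_SIDE = 32
MIN_SEMI_AXIS = 3.0
FEATHER_PX = 2.0


class DimensionError(ValueError):
    """Requested image dimensions are invalid."""


class PlacementError(ValueError):
    """A nodule or marker could not be placed under its constraints."""


class GenerationError(RuntimeError):
    """Dataset generation failed for a specific item."""


@dataclass(frozen=True)
class SpeckleParams:
    """Parameters of the multiplicative speckle background.

    base_mean, base_amp : mean level and amplitude of the smooth echogenicity
        field (intensities); the field is rescaled to span
        ``base_mean ± base_amp``.
    base_scale : Gaussian smoothing scale of the base field, px.
    gamma_shape : shape of the unit-mean gamma noise (variance = 1/shape).
    grain : Gaussian smoothing of the noise field, px (speckle cell size).
        0 keeps the noise i.i.d.
    """

    base_mean: float = 0.50
    base_amp: float = 0.16
    base_scale: float = 14.0
    gamma_shape: float = 4.0
    grain: float = 1.5

    def validate(self) -> None:
        if not (0 < self.base_mean < 1):
            raise ValueError("base_mean must lie in (0, 1)")
        if self.base_amp < 0 or self.base_scale <= 0 or self.grain < 0:
            raise ValueError("speckle parameters must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive (use noise_off() to disable noise)")


def ellipse_half_extents(semi_axes: tuple[float, float], rotation: float) -> tuple[float, float]:
    """Half-width and half-height of the tight axis-aligned box of a rotated ellipse.

    For an ellipse with semi-axes (a, b) rotated by ``rotation``, the extreme
    x (col) offset is sqrt(a^2 cos^2 t + b^2 sin^2 t) and the extreme y (row)
    offset is sqrt(a^2 sin^2 t + b^2 cos^2 t).
    """
    a, b = semi_axes
    c, s = np.cos(rotation), np.sin(rotation)
    half_w = float(np.sqrt((a * c) ** 2 + (b * s) ** 2))
    half_h = float(np.sqrt((a * s) ** 2 + (b * c) ** 2))
    return half_w, half_h


def tight_bbox(center: tuple[float, float], semi_axes: tuple[float, float],
               rotation: float) -> tuple[int, int, int, int]:
    """Tightest integer half-open box containing the rotated ellipse."""
    row, col = center
    half_w, half_h = ellipse_half_extents(semi_axes, rotation)
    x0 = int(np.floor(col - half_w))
    x1 = int(np.ceil(col + half_w))
    y0 = int(np.floor(row - half_h))
    y1 = int(np.ceil(row + half_h))
    return x0, y0, x1, y1


@dataclass(frozen=True)
class Nodule:
    """A hypoechoic elliptical lesion.

    center : (row, col) of the ellipse center, px.
    semi_axes : (a, b) semi-axis lengths, px; both >= 3.
    rotation : radians, counter-clockwise.
    contrast : relative darkening in (0, 1]; interior intensity is
        multiplied by (1 - contrast).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    contrast: float

    def __post_init__(self) -> None:
        if min(self.semi_axes) < MIN_SEMI_AXIS:
            raise ValueError(f"semi-axes must be >= {MIN_SEMI_AXIS}")
        if not (0 <= self.contrast <= 1):
            raise ValueError("contrast must lie in [0, 1]")

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return tight_bbox(self.center, self.semi_axes, self.rotation)

    def to_dict(self) -> dict:
        x0, y0, x1, y1 = self.bbox
        return {
            "bbox": [x0, y0, x1, y1],
            "ellipse": {
                "center": list(self.center),
                "semi_axes": list(self.semi_axes),
                "rotation": self.rotation,
                "contrast": self.contrast,
            },
            "category_id": 1,
        }

    @staticmethod
    def from_dict(d: dict) -> "Nodule":
        e = d["ellipse"]
        return Nodule(center=tuple(e["center"]), semi_axes=tuple(e["semi_axes"]),
                      rotation=e["rotation"], contrast=e["contrast"])


def generate_background(height: int, width: int, speckle: SpeckleParams | None = None,
                        seed: int = 0) -> np.ndarray:
    """Generate a speckle background image, deterministic given ``seed``.

    The image is ``base * noise`` clipped to [0, 1], where ``base`` is a
    Gaussian-smoothed random field rescaled to ``base_mean ± base_amp`` and
    ``noise`` is unit-mean gamma noise of variance ``1/gamma_shape``,
    optionally smoothed by ``grain`` px (which preserves the unit mean).
    """
    if height < MIN_IMAGE_SIDE or width < MIN_IMAGE_SIDE:
        raise DimensionError(f"image sides must be >= {MIN_IMAGE_SIDE}, got {height}x{width}")
    if speckle is None:
        speckle = SpeckleParams()
    speckle.validate()
    rng = np.random.default_rng(seed)

    raw = rng.standard_normal((height, width))
    base = gaussian_filter(raw, speckle.base_scale, mode="reflect")
    span = base.max() - base.min()
    if span > 0:
        base = (base - base.min()) / span  # [0, 1]
    else:
        base = np.full_like(base, 0.5)
    base = speckle.base_mean - speckle.base_amp + 2 * speckle.base_amp * base

    if speckle.gamma_shape == np.inf:
        noise = np.ones_like(base)
    else:
        k = speckle.gamma_shape
        noise = rng.gamma(shape=k, scale=1.0 / k, size=(height, width))
        if speckle.grain > 0:
            noise = gaussian_filter(noise, speckle.grain, mode="reflect")
    return np.clip(base * noise, 0.0, 1.0)


def _ellipse_alpha(shape: tuple[int, int], nodule: Nodule) -> np.ndarray:
    """Soft-edged ellipse membership in [0, 1]; 1 inside, feathered boundary."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    r0, c0 = nodule.center
    th = nodule.rotation
    a, b = nodule.semi_axes
    dc, dr = cols - c0, rows - r0
    # rotate into the ellipse frame (x along semi-axis a)
    x = dc * np.cos(th) + dr * np.sin(th)
    y = -dc * np.sin(th) + dr * np.cos(th)
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
    # approximate signed inward distance in px
    t = (1.0 - rho) * min(a, b)
    return np.clip((t + FEATHER_PX) / FEATHER_PX, 0.0, 1.0)


def place_nodule(image: np.ndarray, nodule: Nodule) -> np.ndarray:
    """Darken the nodule ellipse into a copy of ``image``.

    Interior pixels are multiplied by (1 - contrast); a linear feather of
    ``FEATHER_PX`` px softens the boundary. Pixels farther than the feather
    width outside the bbox are untouched.
    """
    h, w = image.shape
    x0, y0, x1, y1 = nodule.bbox
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise PlacementError(f"nodule bbox {nodule.bbox} outside {h}x{w} image")
    pad = int(np.ceil(FEATHER_PX))
    ry0, ry1 = max(0, y0 - pad), min(h, y1 + pad)
    rx0, rx1 = max(0, x0 - pad), min(w, x1 + pad)
    out = image.copy()
    sub = out[ry0:ry1, rx0:rx1]
    local = Nodule(center=(nodule.center[0] - ry0, nodule.center[1] - rx0),
                   semi_axes=nodule.semi_axes, rotation=nodule.rotation,
                   contrast=nodule.contrast)
    alpha = _ellipse_alpha(sub.shape, local)
    out[ry0:ry1, rx0:rx1] = sub * (1.0 - nodule.contrast * alpha)
    return np.clip(out, 0.0, 1.0)


@dataclass
class PhantomConfig:
    """Dataset generation parameters (desk scale by default)."""

    n_train: int = 200
    n_test: int = 100
    height: int = 128
    width: int = 128
    nodules_per_image: tuple[int, int] = (1, 2)   # inclusive range
    semi_axis_range: tuple[float, float] = (6.0, 14.0)
    contrast_range: tuple[float, float] = (0.10, 0.35)
    # unannotated darker structures (vessels, shadows) that resemble weak
    # nodules; they make texture discrimination realistically imperfect
    distractors_per_image: tuple[int, int] = (1, 3)
    distractor_contrast: tuple[float, float] = (0.04, 0.12)
    border_margin: int = 6
    speckle: SpeckleParams = field(default_factory=SpeckleParams)
    max_attempts: int = 200

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PhantomItem:
    image: np.ndarray
    nodules: list[Nodule]
    split: str  # "train" | "test"
    distractors: list[Nodule] = field(default_factory=list)


@dataclass
class PhantomDataset:
    items: list[PhantomItem]
    seed: int
    config: PhantomConfig

    @property
    def train(self) -> list[PhantomItem]:
        return [it for it in self.items if it.split == "train"]

    @property
    def test(self) -> list[PhantomItem]:
        return [it for it in self.items if it.split == "test"]

    def ground_truth_json(self) -> str:
        """Serialize ground truth as deterministic JSON (COCO-style category 1)."""
        payload = {
            "seed": self.seed,
            "items": [
                {"split": it.split, "nodules": [n.to_dict() for n in it.nodules]}
                for it in self.items
            ],
        }
        return json.dumps(payload, sort_keys=True)


def _boxes_disjoint(box: tuple[int, int, int, int],
                    others: list[tuple[int, int, int, int]]) -> bool:
    x0, y0, x1, y1 = box
    for (u0, v0, u1, v1) in others:
        if x0 < u1 and u0 < x1 and y0 < v1 and v0 < y1:
            return False
    return True


def _sample_nodule(rng: np.random.Generator, config: PhantomConfig,
                   existing: list[tuple[int, int, int, int]],
                   contrast_range: tuple[float, float] | None = None) -> Nodule | None:
    h, w, m = config.height, config.width, config.border_margin
    if contrast_range is None:
        contrast_range = config.contrast_range
    for _ in range(config.max_attempts):
        a = rng.uniform(*config.semi_axis_range)
        b = rng.uniform(*config.semi_axis_range)
        th = rng.uniform(0, np.pi)
        half_w, half_h = ellipse_half_extents((a, b), th)
        if 2 * half_w >= w - 2 * m or 2 * half_h >= h - 2 * m:
            continue
        row = rng.uniform(m + half_h + 1, h - m - half_h - 1)
        col = rng.uniform(m + half_w + 1, w - m - half_w - 1)
        contrast = rng.uniform(*contrast_range)
        nod = Nodule(center=(row, col), semi_axes=(a, b), rotation=th, contrast=contrast)
        if _boxes_disjoint(nod.bbox, existing):
            return nod
    return None


def render_dataset(config: PhantomConfig | None = None, seed: int = 0) -> PhantomDataset:
    """Render a train/test phantom dataset, bit-reproducible from ``seed``.

    Per-image nodule boxes are pairwise disjoint (IoU 0), mirroring a
    one-box-per-nodule annotation scheme. Raises :class:`GenerationError`
    naming the failing image if a nodule cannot be placed.
    """
    if config is None:
        config = PhantomConfig()
    root = np.random.SeedSequence(seed)
    n_total = config.n_train + config.n_test
    child_seeds = root.spawn(n_total)
    items: list[PhantomItem] = []
    for idx in range(n_total):
        rng = np.random.default_rng(child_seeds[idx])
        bg_seed = int(rng.integers(0, 2**31 - 1))
        img = generate_background(config.height, config.width, config.speckle, seed=bg_seed)
        lo, hi = config.nodules_per_image
        n_nod = int(rng.integers(lo, hi + 1))
        nodules: list[Nodule] = []
        for _ in range(n_nod):
            nod = _sample_nodule(rng, config, [n.bbox for n in nodules])
            if nod is None:
                raise GenerationError(f"could not place nodule in image {idx} "
                                      f"after {config.max_attempts} attempts")
            nodules.append(nod)
            img = place_nodule(img, nod)
        # unannotated distractors: darker structures outside every nodule box
        dlo, dhi = config.distractors_per_image
        n_dis = int(rng.integers(dlo, dhi + 1))
        occupied = [n.bbox for n in nodules]
        distractors: list[Nodule] = []
        for _ in range(n_dis):
            dis = _sample_nodule(rng, config, occupied,
                                 contrast_range=config.distractor_contrast)
            if dis is None:
                continue  # crowded image: distractors are best-effort
            occupied.append(dis.bbox)
            distractors.append(dis)
            img = place_nodule(img, dis)
        split = "train" if idx < config.n_train else "test"
        items.append(PhantomItem(image=img, nodules=nodules, split=split,
                                 distractors=distractors))
    return PhantomDataset(items=items, seed=seed, config=config)


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Quantize a [0,1] float image to 8-bit grayscale (round(255*i))."""
    return np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)


def from_uint8(image: np.ndarray) -> np.ndarray:
    return image.astype(np.float64) / 255.0
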