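"""Marker removal by exemplar-based texture synthesis, plus a marker localizer.

The filler is a classical exemplar method in the Efros–Leung family: masked
pixels are synthesized boundary-inward, each copied from the center of the
best-matching known patch (masked-SSD over a square window), with a seeded
uniform tie-break among candidates within a relative tolerance of the
minimum. Candidate patches are drawn from the same image, restricted to
patches containing no originally-masked pixel, so the fill is driven purely
by the surrounding speckle texture.

An optional learned backend (a small dilated-convolution coarse network
trained with a masked l1 reconstruction loss) lives in
:mod:`caliperase.coarse`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import binary_dilation
from skimage.feature import match_template, peak_local_max

from caliperase.annotate import MarkerGlyph, burn_glyphs

PSNR_CAP = 99.0


class InsufficientContextError(ValueError):
    """The mask leaves no usable source texture."""


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class TexSynthParams:
    """Exemplar-synthesis parameters.

    patch_radius : half-width of the square matching window, px.
    search_stride : subsampling stride of the candidate-patch grid (1 =
        every position).
    tolerance : relative SSD slack; all candidates with
        ``ssd <= min_ssd * (1 + tolerance)`` are accepted and one is chosen
        uniformly at random (seeded).
    fill_strategy : "onion_peel" fills boundary layers in scanline order;
        "priority" orders each layer by the number of known pixels in the
        window (most-confident first).
    """

    patch_radius: int = 4
    search_stride: int = 1
    tolerance: float = 0.1
    fill_strategy: str = "onion_peel"

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.fill_strategy not in ("onion_peel", "priority"):
            raise ValueError("fill_strategy must be 'onion_peel' or 'priority'")


@dataclass
class InpaintResult:
    image: np.ndarray
    mask: np.ndarray
    backend: str
    fill_order: np.ndarray | None = None  # per-pixel synthesis rank, -1 outside mask


def _candidate_bank(image: np.ndarray, mask: np.ndarray, params: TexSynthParams
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_cand, P*P) patch matrix, its square, and full-precision center values.

    Candidates are patches fully inside the image whose footprint contains
    no originally-masked pixel, on a ``search_stride`` grid. Matching runs in
    float32 for speed; the synthesized pixel is copied from the float64
    source image.
    """
    p = 2 * params.patch_radius + 1
    s = params.search_stride
    wins = sliding_window_view(image, (p, p))[::s, ::s]
    ok = ~sliding_window_view(mask, (p, p))[::s, ::s].any(axis=(2, 3))
    cand = wins[ok].reshape(-1, p * p).astype(np.float32)
    if cand.shape[0] == 0:
        raise InsufficientContextError("no unmasked candidate patch available")
    rad = params.patch_radius
    centers = image[rad:image.shape[0] - rad:1, rad:image.shape[1] - rad:1][::s, ::s][ok]
    return cand, cand ** 2, centers


def _boundary(unknown: np.ndarray) -> np.ndarray:
    """Unknown pixels with at least one known 8-neighbor."""
    ring = binary_dilation(~unknown) & unknown
    return ring


def inpaint_texture(image: np.ndarray, mask: np.ndarray,
                    params: TexSynthParams | None = None, seed: int = 0
                    ) -> InpaintResult:
    """Fill ``mask`` pixels by exemplar-based texture synthesis.

    Deterministic given ``seed`` (the seed only breaks SSD ties within the
    tolerance band). Pixels outside the mask are returned bit-exact.
    """
    if params is None:
        params = TexSynthParams()
    mask = mask.astype(bool)
    if mask.all():
        raise InsufficientContextError("mask covers the whole image")
    if not mask.any():
        return InpaintResult(image=image.copy(), mask=mask, backend="texture",
                             fill_order=np.full(image.shape, -1, dtype=int))
    rng = np.random.default_rng(seed)
    rad = params.patch_radius
    p = 2 * rad + 1
    cand, cand_sq, center_vals = _candidate_bank(image, mask, params)

    filled = image.copy()
    filled[mask] = 0.0
    known = ~mask
    # padded working copies so window extraction never goes out of bounds
    fpad = np.pad(filled, rad, mode="constant")
    kpad = np.pad(known, rad, mode="constant", constant_values=False)
    order = np.full(image.shape, -1, dtype=int)
    rank = 0

    unknown = mask.copy()
    while unknown.any():
        ring = _boundary(unknown)
        if not ring.any():  # isolated region with no known neighbor: grow anyway
            ring = unknown.copy()
        coords = np.argwhere(ring)
        if params.fill_strategy == "priority":
            conf = np.array([kpad[r:r + p, c:c + p].sum() for r, c in coords])
            idx = np.lexsort((coords[:, 1], coords[:, 0], -conf))
            coords = coords[idx]
        for r, c in coords:
            tw = fpad[r:r + p, c:c + p].reshape(-1).astype(np.float32)
            w = kpad[r:r + p, c:c + p].reshape(-1).astype(np.float32)
            ssd = cand_sq @ w - 2.0 * (cand @ (tw * w)) + float((tw * tw * w).sum())
            np.maximum(ssd, 0.0, out=ssd)  # guard float32 cancellation
            m = float(ssd.min())
            slack = m * (1.0 + params.tolerance) + 1e-9
            pool = np.flatnonzero(ssd <= slack)
            pick = int(pool[rng.integers(0, len(pool))])
            val = float(center_vals[pick])
            filled[r, c] = val
            fpad[r + rad, c + rad] = val
            known[r, c] = True
            kpad[r + rad, c + rad] = True
            order[r, c] = rank
            rank += 1
        unknown &= ~ring
    return InpaintResult(image=filled, mask=mask, backend="texture", fill_order=order)


def locate_markers(image: np.ndarray, glyph_bank: list[MarkerGlyph] | None = None,
                   threshold: float = 0.65) -> np.ndarray:
    """Detect burned-in caliper glyphs by normalized cross-correlation.

    Each glyph template is correlated against the image; local maxima above
    ``threshold`` stamp the glyph footprint into the mask, which is then
    dilated by 1 px to cover anti-aliasing halos. An empty mask is a valid
    output (marker-free image).
    """
    if not glyph_bank:
        glyph_bank = [MarkerGlyph()]
    h, w = image.shape
    mask = np.zeros((h, w), dtype=bool)
    for glyph in glyph_bank:
        size = 2 * glyph.arm_length + 1
        template = np.zeros((size, size))
        template, _ = burn_glyphs(template, [(glyph.arm_length, glyph.arm_length)], glyph)
        corr = match_template(image, template, pad_input=True, mode="reflect")
        corr = np.nan_to_num(corr, nan=0.0)
        peaks = peak_local_max(corr, min_distance=max(2, glyph.arm_length // 2),
                               threshold_abs=threshold, exclude_border=False)
        if len(peaks):
            _, mask = burn_glyphs(np.zeros((h, w)), [tuple(pk) for pk in peaks],
                                  glyph, mask)
    if mask.any():
        mask = binary_dilation(mask, iterations=1)
    return mask


def inpaint_quality(original: np.ndarray, restored: np.ndarray,
                    mask: np.ndarray) -> dict:
    """Masked-region MSE and PSNR (PSNR capped at ``PSNR_CAP`` for MSE 0)."""
    if original.shape != restored.shape or original.shape != mask.shape:
        raise ContractError("shapes must match")
    mask = mask.astype(bool)
    if not mask.any():
        raise ContractError("mask is empty")
    diff = original[mask] - restored[mask]
    mse = float(np.mean(diff ** 2))
    psnr = PSNR_CAP if mse == 0 else min(PSNR_CAP, float(10 * np.log10(1.0 / mse)))
    return {"masked_mse": mse, "masked_psnr": psnr}


def mean_fill(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Baseline: replace masked pixels by the mean of the unmasked pixels."""
    mask = mask.astype(bool)
    out = image.copy()
    out[mask] = image[~mask].mean()
    return out
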