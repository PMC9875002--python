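"""Preprocessing: lesion-centered cropping, masked-histogram CLAHE, the
dual-resolution network input, and training-time augmentation.

The CLAHE variant here excludes near-black scanner background and a small
fraction of extreme intensities from each tile's histogram statistics, so
the contrast budget is spent on the tissue intensities instead of the
background peak; the resulting per-tile mappings are still applied to
every pixel, blended bilinearly between the four nearest tile mappings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BinaryMask, DualInput, GrayImage

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClaheParams:
    """Contrast-limited adaptive histogram equalization parameters.

    ``clip_limit`` is a multiple of the uniform bin height; ``tail_clip``
    is the fraction of extreme intensities dropped from each end of the
    per-tile statistics; pixels below ``background_threshold`` are
    excluded from the statistics entirely.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    n_bins: int = 256
    background_threshold: float = 0.05
    tail_clip: float = 0.005

    def __post_init__(self):
        if self.clip_limit < 1.0:
            raise ValueError(f"clip_limit must be >= 1, got {self.clip_limit}")
        if min(self.tile_grid) < 1:
            raise ValueError(f"tile_grid must be >= (1,1), got {self.tile_grid}")
        if not 0.0 <= self.background_threshold < 1.0:
            raise ValueError(
                f"background_threshold must lie in [0, 1), got "
                f"{self.background_threshold}"
            )
        if not 0.0 <= self.tail_clip < 0.5:
            raise ValueError(f"tail_clip must lie in [0, 0.5), got {self.tail_clip}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")


@dataclass(frozen=True)
class AugmentParams:
    rotation_degrees_range: tuple[float, float] = (-25.0, 25.0)
    noise_sigma: float = 0.02
    mixup_alpha: float = 0.2
    augment_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.augment_probability <= 1.0:
            raise ValueError(
                f"augment_probability outside [0, 1]: {self.augment_probability}"
            )
        if self.mixup_alpha <= 0.0:
            raise ValueError(f"mixup_alpha must be > 0, got {self.mixup_alpha}")
        if self.noise_sigma < 0.0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def center_crop(image: GrayImage, mask: BinaryMask,
                target: tuple[int, int]) -> tuple[GrayImage, BinaryMask]:
    """Crop both arrays to ``target``, centered on the mask centroid.

    Empty masks fall back to the image center; the window is clamped to
    stay inside the image, so a lesion near the edge is never lost to
    clipping of the window itself.
    """
    th, tw = target
    H, W = image.pixels.shape
    if th > H or tw > W:
        raise ValueError(f"crop target {target} exceeds image dims {(H, W)}")
    if mask.pixels.shape != (H, W):
        raise ValueError("image and mask shapes differ")
    if mask.pixels.any():
        cy, cx = ndimage.center_of_mass(mask.pixels)
    else:
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    top = int(round(cy - th / 2.0 + 0.5))
    left = int(round(cx - tw / 2.0 + 0.5))
    top = min(max(top, 0), H - th)
    left = min(max(left, 0), W - tw)
    return (
        GrayImage(image.pixels[top:top + th, left:left + tw]),
        BinaryMask(mask.pixels[top:top + th, left:left + tw]),
    )


def _tile_lut(tile: np.ndarray, params: ClaheParams) -> np.ndarray | None:
    """Clipped-histogram CDF mapping for one tile; None if nothing survives
    the background/tail filtering."""
    valid = tile[tile >= params.background_threshold]
    if params.tail_clip > 0.0 and valid.size:
        lo, hi = np.quantile(valid, [params.tail_clip, 1.0 - params.tail_clip])
        valid = valid[(valid >= lo) & (valid <= hi)]
    if valid.size == 0:
        return None
    nb = params.n_bins
    hist, _ = np.histogram(valid, bins=nb, range=(0.0, 1.0))
    hist = hist.astype(float)
    limit = params.clip_limit * valid.size / nb
    excess = np.maximum(hist - limit, 0.0).sum()
    hist = np.minimum(hist, limit)
    hist += excess / nb        # uniform redistribution of the clipped mass
    cdf = np.cumsum(hist)
    return cdf / cdf[-1]


def clahe(image: GrayImage, params: ClaheParams = ClaheParams()) -> GrayImage:
    """Masked-histogram CLAHE; output rescaled to [0, 1].

    Per-tile CDF mappings are bilinearly interpolated between the four
    neighboring tile centers (clamped at the image edge), which keeps the
    mapping monotone within each tile.
    """
    px = image.pixels
    H, W = px.shape
    tr, tc = params.tile_grid
    nb = params.n_bins
    row_edges = np.linspace(0, H, tr + 1).astype(int)
    col_edges = np.linspace(0, W, tc + 1).astype(int)

    luts = np.empty((tr, tc, nb))
    any_valid = False
    identity = (np.arange(nb) + 0.5) / nb
    for i in range(tr):
        for j in range(tc):
            tile = px[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            lut = _tile_lut(tile, params)
            if lut is None:
                luts[i, j] = identity   # degenerate tile: leave ranks in place
            else:
                luts[i, j] = lut
                any_valid = True
    if not any_valid:
        log.warning("no pixels survived background/tail filtering; "
                    "returning input unchanged")
        return image

    bins = np.minimum((px * nb).astype(int), nb - 1)
    centers_r = (row_edges[:-1] + row_edges[1:]) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:]) / 2.0
    yy = np.arange(H)[:, None].repeat(W, axis=1)
    xx = np.arange(W)[None, :].repeat(H, axis=0)
    fi = np.interp(yy, centers_r, np.arange(tr))
    fj = np.interp(xx, centers_c, np.arange(tc))
    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    i1 = np.minimum(i0 + 1, tr - 1)
    j1 = np.minimum(j0 + 1, tc - 1)
    wi = fi - i0
    wj = fj - j0
    out = ((1 - wi) * (1 - wj) * luts[i0, j0, bins]
           + (1 - wi) * wj * luts[i0, j1, bins]
           + wi * (1 - wj) * luts[i1, j0, bins]
           + wi * wj * luts[i1, j1, bins])
    return GrayImage(np.clip(out, 0.0, 1.0))


def downsample2x_area(pixels: np.ndarray) -> np.ndarray:
    """2x downsampling by 2x2 area averaging (anti-aliased, library-agnostic)."""
    H, W = pixels.shape
    if H % 2 or W % 2:
        raise ValueError(f"dims must be even for 2x downsampling, got {H}x{W}")
    return pixels.reshape(H // 2, 2, W // 2, 2).mean(axis=(1, 3))


def make_dual_input(image: GrayImage, provenance: dict | None = None) -> DualInput:
    """Build the two-resolution network input from one preprocessed image."""
    low = downsample2x_area(image.pixels)
    return DualInput(high_res=image, low_res=GrayImage(np.clip(low, 0.0, 1.0)),
                     provenance=provenance or {})


def augment(image: GrayImage, mask: BinaryMask, params: AugmentParams,
            rng: np.random.Generator) -> tuple[GrayImage, BinaryMask]:
    """Random rotation plus Gaussian intensity noise, applied with
    ``augment_probability``; the mask is rotated with nearest-neighbor
    interpolation and re-binarized so it stays {0, 1}-valued."""
    if image.pixels.shape != mask.pixels.shape:
        raise ValueError("image and mask shapes differ")
    if rng.random() >= params.augment_probability:
        return image, mask
    lo, hi = params.rotation_degrees_range
    angle = float(rng.uniform(lo, hi))
    img = ndimage.rotate(image.pixels, angle, reshape=False, order=1,
                         mode="constant", cval=0.0)
    msk = ndimage.rotate(mask.pixels.astype(float), angle, reshape=False,
                         order=0, mode="constant", cval=0.0)
    if params.noise_sigma > 0.0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    return (
        GrayImage(np.clip(img, 0.0, 1.0)),
        BinaryMask((msk > 0.5).astype(np.uint8)),
    )


def mixup(sample_a: tuple[GrayImage, BinaryMask],
          sample_b: tuple[GrayImage, BinaryMask],
          lam: float | None = None, alpha: float = 0.2,
          rng: np.random.Generator | None = None
          ) -> tuple[GrayImage, np.ndarray]:
    """Convex combination of two samples; returns a soft (real-valued) mask.

    The soft mask feeds the Dice loss directly, which is defined on
    real-valued targets. ``lam`` is drawn from Beta(alpha, alpha) when not
    supplied.
    """
    img_a, msk_a = sample_a
    img_b, msk_b = sample_b
    if img_a.pixels.shape != img_b.pixels.shape:
        raise ValueError("mixup requires matching shapes")
    if lam is None:
        if rng is None:
            raise ValueError("supply either lam or an rng to draw it")
        lam = float(rng.beta(alpha, alpha))
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda outside [0, 1]: {lam}")
    img = lam * img_a.pixels + (1.0 - lam) * img_b.pixels
    soft = lam * msk_a.pixels.astype(float) + (1.0 - lam) * msk_b.pixels.astype(float)
    return GrayImage(img), soft
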