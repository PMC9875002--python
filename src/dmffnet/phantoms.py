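"""Seedable generator of low-contrast lesion phantoms with ground truth.

Emulates the qualitative character of abdominal CT slices around a soft
tissue lesion: a dark scanner-background border, a mid-gray tissue region
with smooth texture, and one or more blob-shaped lesions whose mean
intensity differs from surrounding tissue by only a small offset. Lesions
are ellipses with low-order sinusoidal boundary perturbation, giving the
irregular outlines that make boundary ("detail") segmentation non-trivial
without modeling any CT physics. Every draw is a pure function of the
spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .types import BinaryMask, GrayImage

# smooth-texture correlation length and border darkness, in the units of the
# image; fixed rather than exposed because only their order of magnitude
# matters for exercising the pipeline
_TEXTURE_CORR_PX = 8.0
_BORDER_LEVEL = 0.01
_BORDER_JITTER = 0.005
_MAX_BOUNDARY_WOBBLE = 0.15


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom draw; all intensities in [0, 1], sizes in px."""

    image_height: int = 128
    image_width: int = 128
    border_fraction: float = 0.1
    n_lesions_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (6.0, 18.0)
    tissue_level: float = 0.45
    lesion_contrast: float = 0.12
    texture_sigma: float = 0.02
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.image_height % 32 or self.image_width % 32:
            raise ValueError(
                f"image dims must be divisible by 32 (five halvings), got "
                f"{self.image_height}x{self.image_width}"
            )
        for name in ("tissue_level", "texture_sigma", "noise_sigma",
                     "border_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.lesion_contrast <= 1.0:
            raise ValueError(f"lesion_contrast={self.lesion_contrast} outside [-1, 1]")
        lo, hi = self.n_lesions_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid n_lesions_range {self.n_lesions_range}")
        rlo, rhi = self.lesion_radius_range
        if rlo < 2.0 or rhi < rlo:
            raise ValueError(
                f"lesion radii must be >= 2 px and ordered, got "
                f"{self.lesion_radius_range}"
            )
        interior_h = self.image_height * (1.0 - 2.0 * self.border_fraction)
        interior_w = self.image_width * (1.0 - 2.0 * self.border_fraction)
        r_max = rhi * (1.0 + _MAX_BOUNDARY_WOBBLE)
        if 2.0 * r_max > min(interior_h, interior_w):
            raise ValueError(
                f"max lesion radius {rhi} px does not fit inside the "
                f"{interior_h:.0f}x{interior_w:.0f} px non-border region"
            )

    @property
    def border_px(self) -> tuple[int, int]:
        return (int(round(self.border_fraction * self.image_height)),
                int(round(self.border_fraction * self.image_width)))


def interior_slices(spec: PhantomSpec) -> tuple[slice, slice]:
    """Row/column slices of the non-border (tissue) region."""
    bh, bw = spec.border_px
    return (slice(bh, spec.image_height - bh), slice(bw, spec.image_width - bw))


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """One perturbed-ellipse lesion, guaranteed inside the interior region."""
    H, W = spec.image_height, spec.image_width
    bh, bw = spec.border_px
    rlo, rhi = spec.lesion_radius_range
    a = rng.uniform(rlo, rhi)
    b = rng.uniform(rlo, rhi)
    phi = rng.uniform(0.0, np.pi)
    # boundary wobble: r(theta) = 1 + sum_m eps_m cos(m theta + psi_m), m=2..4
    eps = rng.uniform(0.0, _MAX_BOUNDARY_WOBBLE / 3.0, size=3)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=3)
    margin = max(a, b) * (1.0 + eps.sum())
    cy = rng.uniform(bh + margin, H - bh - margin)
    cx = rng.uniform(bw + margin, W - bw - margin)

    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame and normalize by the semi-axes
    u = (np.cos(phi) * dx + np.sin(phi) * dy) / a
    v = (-np.sin(phi) * dx + np.cos(phi) * dy) / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    wobble = 1.0 + sum(
        e * np.cos(m * theta + p) for m, e, p in zip((2, 3, 4), eps, psi)
    )
    return rho <= wobble


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, BinaryMask]:
    """Draw one phantom image and its exact lesion mask."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    rows, cols = interior_slices(spec)

    mask = np.zeros((H, W), dtype=bool)
    n_lesions = int(rng.integers(spec.n_lesions_range[0],
                                 spec.n_lesions_range[1] + 1))
    for _ in range(n_lesions):
        mask |= _lesion_mask(spec, rng)

    image = np.full((H, W), _BORDER_LEVEL)
    image += rng.normal(0.0, _BORDER_JITTER, size=(H, W))
    interior = np.zeros((H, W), dtype=bool)
    interior[rows, cols] = True

    tissue = np.full((H, W), spec.tissue_level)
    if spec.texture_sigma > 0.0:
        texture = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=(H, W)), _TEXTURE_CORR_PX
        )
        sd = texture.std()
        if sd > 0:
            tissue += texture * (spec.texture_sigma / sd)
    image[interior] = tissue[interior]
    image[mask] += spec.lesion_contrast
    if spec.noise_sigma > 0.0:
        image += rng.normal(0.0, spec.noise_sigma, size=(H, W))
    np.clip(image, 0.0, 1.0, out=image)

    assert not mask[~interior].any(), "lesion escaped the non-border region"
    return GrayImage(image), BinaryMask(mask.astype(np.uint8))


def generate_dataset(spec: PhantomSpec, n_images: int, seed: int
                     ) -> list[tuple[GrayImage, BinaryMask]]:
    """``n_images`` independent phantoms with per-image seeds derived from
    ``seed`` via a splittable seed sequence (order- and count-stable)."""
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images)
    return [
        generate_phantom(replace(spec, seed=int(s & 0x7FFFFFFF)))
        for s in child_seeds
    ]
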