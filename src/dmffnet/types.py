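"""Core image containers: a grayscale slice and its binary lesion mask."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GrayImage:
    """A 2D intensity slice with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"intensities must lie in [0, 1], got range "
                f"[{px.min():.4g}, {px.max():.4g}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} ground-truth mask with the same shape as its image."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D mask, got shape {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class DualInput:
    """Paired full- and half-resolution views of one preprocessed image."""

    high_res: GrayImage
    low_res: GrayImage
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.high_res.height != 2 * self.low_res.height
                or self.high_res.width != 2 * self.low_res.width):
            raise ValueError(
                f"low-res view {self.low_res.pixels.shape} is not exactly half "
                f"of high-res {self.high_res.pixels.shape}"
            )
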