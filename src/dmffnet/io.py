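"""Readers/writers for the image formats the pipeline touches, plus run
manifests for bit-identical re-runs.

Supported formats: 8/16-bit grayscale PNG and TIFF, and single-slice
NIfTI. Intensities are scaled to [0, 1] by the integer format's full
range; masks are binarized at half range. Masks live as 0/255 on disk and
{0, 1} in memory; 8-bit export rounds half to even.
"""

from __future__ import annotations

import hashlib
import json
import platform
import subprocess
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from . import __version__
from .types import BinaryMask, GrayImage

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _load_gray(path: Path) -> np.ndarray:
    """Load a 2D grayscale array scaled to [0, 1]."""
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(
                f"{path}: expected a single-slice NIfTI, got shape {data.shape}"
            )
        data = data.astype(float)
        lo, hi = float(data.min()), float(data.max())
        if lo < 0.0 or hi > 1.0:   # raw scanner units: rescale by range
            data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
        return data
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: RGB input not supported; convert to grayscale")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}; use 8/16-bit grayscale")


def read_image_pair(image_path, mask_path) -> tuple[GrayImage, BinaryMask]:
    """Read an image and its mask, enforcing shape agreement."""
    img = _load_gray(Path(image_path))
    msk = _load_gray(Path(mask_path))
    if img.shape != msk.shape:
        raise ValueError(
            f"shape mismatch: image {img.shape} vs mask {msk.shape}"
        )
    return GrayImage(np.clip(img, 0.0, 1.0)), BinaryMask((msk >= 0.5).astype(np.uint8))


def write_gray(pixels: np.ndarray, path, depth: int = 8) -> None:
    """Write a [0, 1] array as 8- or 16-bit grayscale; half rounds to even."""
    path = Path(path)
    px = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    if depth == 8:
        iio.imwrite(path, np.round(px * 255.0).astype(np.uint8))
    elif depth == 16:
        iio.imwrite(path, np.round(px * 65535.0).astype(np.uint16))
    else:
        raise ValueError(f"depth must be 8 or 16, got {depth}")


def write_mask(mask: BinaryMask | np.ndarray, path) -> None:
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    iio.imwrite(Path(path), (px.astype(np.uint8) * 255))


def write_prediction(mask_soft: np.ndarray, out_path, threshold: float = 0.5
                     ) -> tuple[Path, Path]:
    """Write the soft probability map (16-bit) and its thresholded binary
    mask (0/255, 8-bit); returns both paths."""
    soft = np.asarray(mask_soft, dtype=float)
    if soft.min() < 0.0 or soft.max() > 1.0:
        raise ValueError("soft mask values must lie in [0, 1]")
    out_path = Path(out_path)
    stem = out_path.name
    for suffix in (".png", ".tif", ".tiff"):
        if stem.lower().endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    soft_path = out_path.with_name(f"{stem}_soft.png")
    hard_path = out_path.with_name(f"{stem}_mask.png")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_gray(soft, soft_path, depth=16)
    write_mask((soft >= threshold).astype(np.uint8), hard_path)
    return soft_path, hard_path


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a command bit-identically on one device."""

    command: str
    config: dict
    seeds: dict
    input_hashes: dict = field(default_factory=dict)
    code_version: str = __version__
    platform: str = platform.platform()
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)
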