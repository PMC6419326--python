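"""Image and field I/O helpers (PNG/TIFF/JPEG via imageio/tifffile)."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from leeac.errors import ParameterError
from leeac.preprocess import PatchSpec

__all__ = ["read_image", "read_mask", "write_mask", "write_field", "write_field_preview",
           "read_patch_json", "write_patch_json"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit image; drops an alpha channel if present."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return img


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask stored as a {0, 255} (or {0,1}) single-channel PNG."""
    m = np.asarray(iio.imread(path))
    if m.ndim == 3:
        m = m[..., 0]
    return (m > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as a single-channel {0,255} PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ParameterError("mask must be 2-D")
    iio.imwrite(path, (mask > 0).astype(np.uint8) * 255)


def write_field(path: str | Path, field: np.ndarray) -> None:
    """Write a real-valued field as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(field, dtype=np.float32))


def write_field_preview(path: str | Path, field: np.ndarray) -> None:
    """Write an 8-bit preview PNG of a field (linear min-max rescale)."""
    f = np.asarray(field, dtype=np.float64)
    lo, hi = f.min(), f.max()
    scaled = np.zeros_like(f) if hi == lo else (f - lo) / (hi - lo)
    iio.imwrite(path, (scaled * 255).astype(np.uint8))


def read_patch_json(path: str | Path) -> PatchSpec:
    with open(path) as fh:
        return PatchSpec.from_dict(json.load(fh))


def write_patch_json(path: str | Path, patch: PatchSpec) -> None:
    with open(path, "w") as fh:
        json.dump(patch.to_dict(), fh, indent=2)
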