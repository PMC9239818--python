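"""Readers and writers for grayscale images and label maps.

Supported containers: PNG (8/16-bit gray), PGM, and single-slice NIfTI-1.
Intensities are normalized to [0, 1] by the container's bit-depth maximum
(8-bit -> /255), never per-image min-max, so noise and bandwidth parameters
keep their meaning across images.  Label maps are stored verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

__all__ = ["GrayImage", "read_image", "write_image", "write_labels", "read_labels"]

_PIL_BITDEPTH = {"L": 8, "I;16": 16, "I": 16}


@dataclass
class GrayImage:
    """A 2-D raster of normalized intensities in [0, 1]."""

    pixels: np.ndarray
    source_bitdepth: int = 8
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(
    path,
    slice_axis: int = -1,
    slice_index: int | None = None,
) -> GrayImage:
    """Read a grayscale image, normalized to [0, 1] by container bit depth.

    NIfTI volumes are read slice-wise: ``slice_index`` is required for 3-D
    data (default slice axis: last).  RGB/multichannel rasters are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        return _read_nifti(path, slice_axis, slice_index)
    if path.suffix.lower() not in (".png", ".pgm"):
        raise ValueError(f"unsupported format: {path.suffix!r} (PNG, PGM, NIfTI)")
    img = Image.open(path)
    if img.mode not in _PIL_BITDEPTH:
        raise ValueError(
            f"RGB/multichannel input not supported (mode {img.mode!r}); "
            "convert to grayscale first"
        )
    depth = _PIL_BITDEPTH[img.mode]
    arr = np.asarray(img, dtype=np.float64) / (2**depth - 1)
    return GrayImage(np.clip(arr, 0.0, 1.0), depth, {"path": str(path)})


def _read_nifti(path: Path, slice_axis: int, slice_index: int | None) -> GrayImage:
    vol = nib.load(str(path))
    data = np.asanyarray(vol.dataobj)
    data = np.squeeze(data)
    if data.ndim == 3:
        if slice_index is None:
            raise ValueError("a slice index is required for 3-D NIfTI volumes")
        axis = slice_axis % 3
        if not 0 <= slice_index < data.shape[axis]:
            raise ValueError(
                f"slice index {slice_index} out of range for axis {axis} "
                f"(size {data.shape[axis]})"
            )
        data = np.take(data, slice_index, axis=axis)
    elif data.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D NIfTI data, got {data.ndim}-D")
    if np.issubdtype(data.dtype, np.integer):
        depth = 8 * data.dtype.itemsize
        arr = data.astype(np.float64) / (2**depth - 1)
    else:
        depth = 16
        arr = data.astype(np.float64)
    return GrayImage(
        np.clip(arr, 0.0, 1.0),
        depth,
        {"path": str(path), "slice_axis": slice_axis, "slice_index": slice_index},
    )


def write_image(image, path, bitdepth: int = 8) -> None:
    """Write normalized intensities as 8/16-bit PNG, 8-bit PGM, or NIfTI."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(pixels[..., None].astype(np.float32), np.eye(4)), str(path))
        return
    if bitdepth not in (8, 16):
        raise ValueError("bitdepth must be 8 or 16")
    scaled = np.round(np.clip(pixels, 0, 1) * (2**bitdepth - 1))
    if bitdepth == 8:
        Image.fromarray(scaled.astype(np.uint8), mode="L").save(path)
    else:
        if path.suffix.lower() == ".pgm":
            raise ValueError("16-bit PGM output not supported; use PNG")
        Image.fromarray(scaled.astype(np.uint32), mode="I").convert("I;16").save(path)


def write_labels(labels: np.ndarray, path, colorize: bool = False) -> None:
    """Store label integers verbatim (8-bit PNG/PGM for <=256 labels, or
    NIfTI for any count); optionally write a stretched companion PNG for
    viewing."""
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("labels must be nonnegative")
    path = Path(path)
    if _is_nifti(path):
        nib.save(
            nib.Nifti1Image(labels[..., None].astype(np.int32), np.eye(4)), str(path)
        )
        return
    if labels.max() > 255:
        raise ValueError("more than 256 labels; use NIfTI output")
    Image.fromarray(labels.astype(np.uint8), mode="L").save(path)
    if colorize:
        k = int(labels.max())
        view = (labels * (255 // max(k, 1))).astype(np.uint8)
        Image.fromarray(view, mode="L").save(path.with_name(path.stem + "_view.png"))


def read_labels(path, slice_axis: int = -1, slice_index: int | None = None) -> np.ndarray:
    """Read a label map written by :func:`write_labels` (verbatim integers)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data = np.squeeze(np.asanyarray(nib.load(str(path)).dataobj))
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError("a slice index is required for 3-D NIfTI volumes")
            data = np.take(data, slice_index, axis=slice_axis % 3)
        return data.astype(np.int32)
    img = Image.open(path)
    if img.mode not in _PIL_BITDEPTH:
        raise ValueError(f"label image must be single-channel, got mode {img.mode!r}")
    return np.asarray(img).astype(np.int32)
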