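"""Grayscale image loading, normalization, resizing and persistence.

Every stage of the pipeline exchanges :class:`GrayImage` objects: 2-D
float64 intensity grids in [0, 1], row-major with the origin at the
top-left corner (0-based indices). Input formats are PNG/JPEG (via
Pillow) and single-slice NIfTI (via nibabel, middle axial slice when the
volume is 3-D); output is lossless grayscale PNG (8- or 16-bit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = ["GrayImage", "load_image", "save_image"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass(frozen=True)
class GrayImage:
    """A 2-D intensity grid in [0, 1] with an optional pixel spacing.

    Parameters
    ----------
    pixels
        2-D float array; intensities must be finite and in [0, 1].
    spacing_mm
        Physical size of one pixel in millimetres (isotropic). Used by
        the morphology stage to convert a structuring-element radius
        from mm to pixels. Default 1.0.
    """

    pixels: np.ndarray
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _minmax_scale(arr: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; zero-variance input maps to all zeros."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo == 0.0:
        return np.zeros_like(arr, dtype=np.float64)
    return (arr - lo) / (hi - lo)


def _read_raw(path: Path) -> np.ndarray:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        vol = np.squeeze(vol)
        if vol.ndim == 3:  # middle axial slice
            vol = vol[:, :, vol.shape[2] // 2]
        if vol.ndim != 2:
            raise OSError(f"cannot extract a 2-D slice from {path}")
        return vol
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64)
    if arr.ndim == 3:  # collapse RGB(A) to luminance = channel mean
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise OSError(f"{path} did not decode to a 2-D image")
    return arr


def load_image(
    path: str | Path,
    target_size: tuple[int, int] | None = None,
    spacing_mm: float = 1.0,
) -> GrayImage:
    """Load a grayscale image, normalize to [0, 1] and optionally resize.

    RGB input is collapsed to luminance (channel mean), intensities are
    min-max scaled to [0, 1] (a constant image maps to all zeros) and the
    grid is resampled to ``target_size = (height, width)`` by anti-aliased
    bilinear interpolation.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    arr = _minmax_scale(_read_raw(path))
    if target_size is not None:
        h, w = int(target_size[0]), int(target_size[1])
        if h < 8 or w < 8:
            raise ValueError("target_size must be at least 8x8")
        if (h, w) != arr.shape:
            arr = _sk_resize(arr, (h, w), order=1, anti_aliasing=True,
                             preserve_range=True)
            arr = np.clip(arr, 0.0, 1.0)
    return GrayImage(arr, spacing_mm=spacing_mm)


def save_image(img: GrayImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write a GrayImage as a lossless grayscale PNG.

    ``bit_depth`` 8 or 16; a save/load round trip is exact to within the
    quantization step (1/255 or 1/65535).
    """
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"parent directory does not exist: {path.parent}")
    if bit_depth == 8:
        data = np.round(img.pixels * 255.0).astype(np.uint8)
        Image.fromarray(data, mode="L").save(path, format="PNG")
    elif bit_depth == 16:
        data = np.round(img.pixels * 65535.0).astype(np.uint16)
        Image.fromarray(data).save(path, format="PNG")
    else:
        raise ValueError("bit_depth must be 8 or 16")
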