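"""Directional translation augmentation for training images.

Training sets are expanded with left/right/up/down translations of each
image; vacated strips are zero-filled (brain MRI background is black).
Translations preserve anatomy, unlike rotations or elastic warps, which
is why they are the only augmentation offered. Augmentation is a
training-time operation only — evaluation harnesses must never apply it
to test folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import GrayImage

__all__ = ["ShiftSpec", "DIRECTIONS", "shift", "augment_set"]

DIRECTIONS = ("left", "right", "up", "down")


@dataclass(frozen=True)
class ShiftSpec:
    direction: str
    offset_px: int

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.offset_px < 1:
            raise ValueError("offset_px must be a positive integer")

    def validate_for(self, img: GrayImage) -> None:
        if self.offset_px >= min(img.height, img.width) / 2:
            raise ValueError(
                f"offset {self.offset_px} too large for "
                f"{img.height}x{img.width} image"
            )


def shift(img: GrayImage, spec: ShiftSpec) -> GrayImage:
    """Translate by ``offset_px`` in the given direction, zero-filling."""
    spec.validate_for(img)
    d, px = spec.direction, spec.offset_px
    out = np.zeros_like(img.pixels)
    if d == "left":
        out[:, :-px] = img.pixels[:, px:]
    elif d == "right":
        out[:, px:] = img.pixels[:, :-px]
    elif d == "up":
        out[:-px, :] = img.pixels[px:, :]
    else:  # down
        out[px:, :] = img.pixels[:-px, :]
    return GrayImage(out, spacing_mm=img.spacing_mm)


def augment_set(imgs: list[GrayImage], offset_px: int = 8) -> list[GrayImage]:
    """Return originals plus all four directional variants (5x the input).

    The order is [original, left, right, up, down] per image, so labels
    can be replicated with ``np.repeat(labels, 5)``.
    """
    if not imgs:
        raise ValueError("augment_set requires a non-empty image list")
    out: list[GrayImage] = []
    for img in imgs:
        out.append(img)
        for d in DIRECTIONS:
            out.append(shift(img, ShiftSpec(d, offset_px)))
    return out
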