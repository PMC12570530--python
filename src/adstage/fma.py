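"""Morphological-gradient segmentation and mild/advanced staging.

Detected AD images are segmented by a flat grayscale morphological
gradient: dilation (neighborhood maximum) and erosion (neighborhood
minimum) with a disk structuring element of physical radius 0.5 mm are
computed over replicated borders, and the affected-pixel (AP) map is
the thresholded difference DI − EI, which is non-negative everywhere
and large where local intensity changes sharply — degraded tissue
boundaries. The default threshold is automatic (Otsu's
variance-maximizing split of the gradient histogram) with a manual
override.

Staging trains a second feature-extractor + FCM stack on AP-masked
images (image times binary mask, full frame, geometry unchanged) of
mild vs advanced cases, and assigns one of the two stage labels to new
AD images. Staging is only meaningful for images the detection stage
labelled AD; routing a non-AD image here is a caller contract violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imgio import GrayImage
from .pipeline import ClassifierConfig, FeatureClassifier

__all__ = [
    "StructuringElement",
    "APMask",
    "StagingModel",
    "dilate",
    "erode",
    "ap_segment",
    "fit_staging",
    "stage_classify",
]

STAGES = ("mild", "advanced")


@dataclass(frozen=True)
class StructuringElement:
    """Disk structuring element specified by a physical radius in mm.

    The pixel radius is round(radius_mm / spacing_mm), floored at 1, so
    with the default 1 mm/px spacing the 0.5 mm disk degenerates to the
    radius-1 plus-shaped disk.
    """

    radius_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")

    def radius_px(self, spacing_mm: float) -> int:
        return max(1, round(self.radius_mm / spacing_mm))

    def footprint(self, spacing_mm: float) -> np.ndarray:
        r = self.radius_px(spacing_mm)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        return (yy * yy + xx * xx) <= r * r


@dataclass(frozen=True)
class APMask:
    """Binary affected-pixel mask with the gradient it was cut from."""

    mask: np.ndarray
    gradient: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        if self.mask.shape != self.gradient.shape:
            raise ValueError("mask and gradient shapes differ")

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


def _check_fit(img: GrayImage, se: StructuringElement) -> np.ndarray:
    fp = se.footprint(img.spacing_mm)
    if fp.shape[0] > img.height or fp.shape[1] > img.width:
        raise ValueError("structuring element larger than image")
    return fp


def dilate(img: GrayImage, se: StructuringElement) -> GrayImage:
    """Flat grayscale dilation: per-pixel disk-neighborhood maximum."""
    fp = _check_fit(img, se)
    out = ndimage.grey_dilation(img.pixels, footprint=fp, mode="nearest")
    return GrayImage(out, spacing_mm=img.spacing_mm)


def erode(img: GrayImage, se: StructuringElement) -> GrayImage:
    """Flat grayscale erosion: per-pixel disk-neighborhood minimum."""
    fp = _check_fit(img, se)
    out = ndimage.grey_erosion(img.pixels, footprint=fp, mode="nearest")
    return GrayImage(out, spacing_mm=img.spacing_mm)


def ap_segment(
    img: GrayImage,
    se: StructuringElement | None = None,
    threshold: float | str = "auto",
) -> APMask:
    """Affected-pixel segmentation by the morphological gradient DI − EI.

    ``threshold='auto'`` applies Otsu's variance-maximizing threshold to
    the gradient values; a constant image yields a zero gradient and an
    empty mask. A numeric threshold is used as-is (mask = gradient >
    threshold).
    """
    se = se if se is not None else StructuringElement()
    grad = dilate(img, se).pixels - erode(img, se).pixels
    # max-min is >= 0 mathematically; clip defensive float residue
    grad = np.maximum(grad, 0.0)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError("threshold must be a number or 'auto'")
        if float(grad.max()) == float(grad.min()):
            thr = float(grad.max())  # flat gradient -> empty mask
        else:
            thr = float(threshold_otsu(grad))
    else:
        thr = float(threshold)
    return APMask(mask=grad > thr, gradient=grad, threshold_used=thr)


@dataclass
class StagingModel:
    """Feature-extractor + FCM pair fitted on AP-masked mild/advanced images."""

    classifier: FeatureClassifier

    @property
    def fitted(self) -> bool:
        return self.classifier.fitted

    def save(self, path) -> None:
        from .pipeline import _classifier_payload

        np.savez(path, **_classifier_payload(self.classifier))

    @classmethod
    def load(cls, path) -> "StagingModel":
        from .pipeline import _classifier_from_payload

        with np.load(path, allow_pickle=False) as data:
            clf = _classifier_from_payload(data)
        return cls(classifier=clf)


def _masked(img: GrayImage, mask) -> GrayImage:
    m = mask.mask if isinstance(mask, APMask) else np.asarray(mask)
    if m.shape != img.pixels.shape:
        raise ValueError("mask shape does not match image")
    return GrayImage(img.pixels * m.astype(np.float64),
                     spacing_mm=img.spacing_mm)


def fit_staging(
    mild_imgs: list[GrayImage],
    advanced_imgs: list[GrayImage],
    mild_masks,
    advanced_masks,
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
) -> StagingModel:
    """Train the staging stack on AP-masked images of both stages.

    Masks must align one-to-one with their image lists. The masked
    images (full frame, not crops) are fed to a fresh
    :class:`FeatureClassifier`; the fitted cluster -> stage map emits
    exactly one of {mild, advanced}.
    """
    if not mild_imgs or not advanced_imgs:
        raise ValueError("both stage classes must be non-empty")
    if len(mild_imgs) != len(mild_masks) or len(advanced_imgs) != len(advanced_masks):
        raise ValueError("masks must align with images")
    imgs = [_masked(i, m) for i, m in zip(mild_imgs, mild_masks)]
    imgs += [_masked(i, m) for i, m in zip(advanced_imgs, advanced_masks)]
    labels = ["mild"] * len(mild_imgs) + ["advanced"] * len(advanced_imgs)
    cfg = cfg if cfg is not None else ClassifierConfig()
    clf = FeatureClassifier(cfg, seed=seed).fit(imgs, labels)
    return StagingModel(classifier=clf)


def stage_classify(
    model: StagingModel,
    img: GrayImage,
    mask,
    detection_label: str = "AD",
) -> str:
    """Stage one detected-AD image as 'mild' or 'advanced'.

    ``detection_label`` is the label the detection stage produced;
    anything other than 'AD' is a pipeline contract violation. An empty
    mask still yields a label (the masked image is all zeros), which
    callers should treat as low-confidence.
    """
    if not model.fitted:
        raise ValueError("staging model is not fitted")
    if detection_label != "AD":
        raise ValueError(
            "staging is only defined for images detected as AD "
            f"(got detection label {detection_label!r})"
        )
    _, label = model.classifier.predict_one(_masked(img, mask))
    return label
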