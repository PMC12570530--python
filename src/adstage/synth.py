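"""Synthetic 2-D brain phantoms with ground-truth class, stage and mask.

The generator renders an axial-slice caricature of a T1 brain image: an
elliptical head with a bright cortical ribbon, mid-intensity tissue, and
a pair of dark central ventricles. Alzheimer's-like atrophy is emulated
by the two canonical visual signatures — ventricular enlargement and
cortical-band thinning — controlled by ``ventricle_scale`` (area factor;
1.0 = healthy, defaults 1.4 mild / 2.2 advanced) with optional boundary
roughening. The ground-truth affected-pixel mask is the enlargement
band: pixels inside the atrophied ventricle outline but outside the
healthy (scale 1.0) outline. Additive Gaussian noise is applied last and
intensities are clipped to [0, 1]. Every phantom is fully determined by
its seed.

These phantoms carry class-separable gross structure, not anatomical
realism: no gyri, no skull inhomogeneity, no Rician noise floor, no
scanner bias field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .imgio import GrayImage

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "make_phantom",
    "make_dataset",
    "MILD_VENTRICLE_SCALE",
    "ADVANCED_VENTRICLE_SCALE",
]

MILD_VENTRICLE_SCALE = 1.4
ADVANCED_VENTRICLE_SCALE = 2.2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom.

    ``ventricle_scale`` multiplies the healthy ventricle area;
    ``boundary_roughness`` is the relative amplitude of smooth angular
    perturbation of the ventricle outline; ``contrast`` scales all
    tissue intensities; ``noise_sigma`` is the additive Gaussian noise
    standard deviation on the [0, 1] scale.
    """

    size: int = 64
    class_label: str = "NAD"
    stage: str = "none"
    ventricle_scale: float = 1.0
    boundary_roughness: float = 0.0
    noise_sigma: float = 0.02
    contrast: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in ("AD", "NAD"):
            raise ValueError("class_label must be 'AD' or 'NAD'")
        if self.stage not in ("mild", "advanced", "none"):
            raise ValueError("stage must be 'mild', 'advanced' or 'none'")
        if (self.stage == "none") != (self.class_label == "NAD"):
            raise ValueError("stage must be 'none' iff class_label is 'NAD'")
        if self.ventricle_scale < 1.0:
            raise ValueError("ventricle_scale must be >= 1")
        if self.boundary_roughness < 0:
            raise ValueError("boundary_roughness must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")


@dataclass(frozen=True)
class PhantomDataset:
    """A balanced labelled phantom collection (NAD / mild AD / advanced AD)."""

    images: tuple[GrayImage, ...]
    class_labels: tuple[str, ...]
    stage_labels: tuple[str, ...]
    masks: tuple[np.ndarray, ...]
    specs: tuple[PhantomSpec, ...]

    def __len__(self) -> int:
        return len(self.images)


def _smooth_angular_noise(rng: np.random.Generator, phi: np.ndarray,
                          n_harmonics: int = 4) -> np.ndarray:
    """Smooth zero-mean periodic perturbation g(phi) with |g| <~ 1."""
    g = np.zeros_like(phi)
    for k in range(1, n_harmonics + 1):
        a, b = rng.normal(size=2)
        g += (a * np.cos(k * phi) + b * np.sin(k * phi)) / k
    return g / n_harmonics


def _ventricle_inside(yy, xx, cy, cx, ry, rx, offset, sign, rough_field):
    """Boolean inside-test for one ventricle lobe (sign = left/right).

    ``offset`` is the lateral lobe-centre displacement; it stays fixed
    as atrophy scales the axes, so enlargement grows around the same
    midline position as in the healthy brain.
    """
    dy = (yy - cy) / ry
    dx = (xx - (cx + sign * offset)) / rx
    rho = np.sqrt(dy * dy + dx * dx)
    return rho <= 1.0 + rough_field


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, np.ndarray]:
    """Render one phantom; returns the image and the boolean true-AP mask."""
    if spec.size < 32:
        raise ValueError("phantom size must be >= 32")
    n = spec.size
    rng = np.random.default_rng(spec.seed)

    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = n / 2 + rng.uniform(-0.02, 0.02) * n
    cx = n / 2 + rng.uniform(-0.02, 0.02) * n
    head_ry = 0.42 * n * (1 + rng.uniform(-0.03, 0.03))
    head_rx = 0.36 * n * (1 + rng.uniform(-0.03, 0.03))
    rho_head = np.sqrt(((yy - cy) / head_ry) ** 2 + ((xx - cx) / head_rx) ** 2)
    head = rho_head <= 1.0

    # cortical ribbon thins as atrophy progresses
    ribbon_frac = 0.14 / spec.ventricle_scale
    ribbon = head & (rho_head >= 1.0 - ribbon_frac)

    # ventricles: two mirrored lobes; axes scale with sqrt(area factor)
    base_ry = 0.11 * n * (1 + rng.uniform(-0.05, 0.05))
    base_rx = 0.05 * n * (1 + rng.uniform(-0.05, 0.05))
    lin = math.sqrt(spec.ventricle_scale)
    phi = np.arctan2(yy - cy, xx - cx)
    rough = spec.boundary_roughness * _smooth_angular_noise(rng, phi)

    offset = 1.6 * base_rx
    vent = np.zeros((n, n), dtype=bool)
    vent_base = np.zeros((n, n), dtype=bool)
    for sign in (-1.0, 1.0):
        vent |= _ventricle_inside(yy, xx, cy, cx, base_ry * lin,
                                  base_rx * lin, offset, sign, rough)
        vent_base |= _ventricle_inside(yy, xx, cy, cx, base_ry,
                                       base_rx, offset, sign,
                                       np.zeros_like(rough))
    vent &= head
    vent_base &= head

    c = spec.contrast
    img = np.zeros((n, n), dtype=np.float64)
    img[head] = 0.55 * c
    img[ribbon] = 0.85 * c
    img[vent] = 0.08 * c

    if spec.class_label == "AD":
        mask = vent & ~vent_base
    else:
        mask = np.zeros((n, n), dtype=bool)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return GrayImage(img), mask


def make_dataset(
    n_per_group: int,
    base: PhantomSpec | None = None,
    seed: int = 0,
    mild_scale: float = MILD_VENTRICLE_SCALE,
    advanced_scale: float = ADVANCED_VENTRICLE_SCALE,
) -> PhantomDataset:
    """Generate balanced NAD / mild-AD / advanced-AD groups.

    Per-sample seeds are drawn from the master ``seed``, so two master
    seeds give different pixel content but identical label structure.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    base = base if base is not None else PhantomSpec()
    rng = np.random.default_rng(seed)

    groups = [
        ("NAD", "none", 1.0),
        ("AD", "mild", mild_scale),
        ("AD", "advanced", advanced_scale),
    ]
    images, cls, stg, masks, specs = [], [], [], [], []
    for class_label, stage, vscale in groups:
        for _ in range(n_per_group):
            s = replace(
                base,
                class_label=class_label,
                stage=stage,
                ventricle_scale=vscale,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, mask = make_phantom(s)
            images.append(img)
            cls.append(class_label)
            stg.append(stage)
            masks.append(mask)
            specs.append(s)
    return PhantomDataset(
        images=tuple(images),
        class_labels=tuple(cls),
        stage_labels=tuple(stg),
        masks=tuple(masks),
        specs=tuple(specs),
    )
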