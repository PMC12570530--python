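"""Oriented Gabor kernel bank and max-fusion texture transform.

The pipeline's preprocessing step converts spatial pixel structure into
spatial-frequency texture responses: an image is convolved with a bank
of even-symmetric (cosine-phase) Gabor kernels

    GK(x, y) = exp(-[ (x1/s)^2 + (y1/s)^2 ] / 2) * cos(2*pi*f_c*x1)

where (x1, y1) are the pixel offsets rotated by the orientation theta,

    x1 = x*cos(theta) + y*sin(theta)
    y1 = y*cos(theta) - x*sin(theta),

s is the spatial factor of the Gaussian envelope and f_c the carrier
frequency in cycles/pixel. Orientations sweep a half-open 180-degree
range in 1-degree steps by default, giving exactly 180 kernels per
(s, f) pair; the per-kernel responses are fused by a per-pixel maximum
and min-max rescaled to [0, 1].

The integer "frequency factors" {1, 2, 3, 4} of the bank are mapped to
cycles/pixel by ``freq_scale`` (default 0.1): taken literally as
cycles/pixel they would alias on a discrete grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import GrayImage

__all__ = [
    "GaborParams",
    "GaborKernel",
    "GaborBank",
    "rotate_coordinates",
    "gabor_kernel",
    "build_bank",
    "apply_fgt",
]


@dataclass(frozen=True)
class GaborParams:
    """Configuration of the Gabor bank.

    Defaults follow the pipeline's standard setting: spatial factor 1,
    frequency factors {1, 2, 3, 4}, orientations theta in [-90, 90)
    degrees stepped by 1 degree (180 per frequency), carrier scale 0.1
    cycles/pixel per unit frequency factor, and a fixed square support
    of half-width 7 pixels (the envelope is < 1e-3 beyond ~3*s).
    """

    s: float = 1.0
    freqs: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    theta_start: float = -90.0
    theta_stop: float = 90.0
    theta_step: float = 1.0
    freq_scale: float = 0.1
    support_radius: int = 7

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("spatial factor s must be positive")
        if len(self.freqs) == 0:
            raise ValueError("freqs must be non-empty")
        if any(f <= 0 for f in self.freqs):
            raise ValueError("frequency factors must be positive")
        if self.theta_step <= 0:
            raise ValueError("theta_step must be positive")
        span = (self.theta_stop - self.theta_start) / self.theta_step
        if span <= 0 or abs(span - round(span)) > 1e-9:
            raise ValueError("orientation span must be a positive multiple of theta_step")
        if self.freq_scale <= 0:
            raise ValueError("freq_scale must be positive")
        if self.support_radius < 1:
            raise ValueError("support_radius must be >= 1")

    @property
    def n_orientations(self) -> int:
        """Orientation count over the half-open range [start, stop)."""
        return int(round((self.theta_stop - self.theta_start) / self.theta_step))

    @property
    def thetas(self) -> np.ndarray:
        return self.theta_start + self.theta_step * np.arange(self.n_orientations)


@dataclass(frozen=True)
class GaborKernel:
    """A single oriented kernel: a (2r+1) x (2r+1) weight grid."""

    weights: np.ndarray
    theta: float
    f: float
    s: float


@dataclass(frozen=True)
class GaborBank:
    """Ordered kernel list, outer loop over frequency, inner over theta."""

    kernels: tuple[GaborKernel, ...]
    params: GaborParams

    def __len__(self) -> int:
        return len(self.kernels)


def rotate_coordinates(x: float, y: float, theta: float) -> tuple[float, float]:
    """Rotate offset coordinates by ``theta`` degrees.

    Returns (x1, y1) with x1 = x cos(theta) + y sin(theta) and
    y1 = y cos(theta) - x sin(theta); the Euclidean norm is preserved.
    """
    t = math.radians(theta)
    ct, st = math.cos(t), math.sin(t)
    return x * ct + y * st, y * ct - x * st


def gabor_kernel(params: GaborParams, f: float, theta: float) -> GaborKernel:
    """Evaluate one even-symmetric Gabor kernel on the support square.

    The weight at integer offset (x, y) is
    exp(-((x1/s)^2 + (y1/s)^2)/2) * cos(2*pi*(f*freq_scale)*x1); the
    centre weight is always exactly 1 and w(x, y) = w(-x, -y).
    """
    r = params.support_radius
    offs = np.arange(-r, r + 1, dtype=np.float64)
    # row index = y offset (down), column index = x offset (right)
    yy, xx = np.meshgrid(offs, offs, indexing="ij")
    t = math.radians(theta)
    ct, st = math.cos(t), math.sin(t)
    x1 = xx * ct + yy * st
    y1 = yy * ct - xx * st
    envelope = np.exp(-0.5 * ((x1 / params.s) ** 2 + (y1 / params.s) ** 2))
    carrier = np.cos(2.0 * math.pi * (f * params.freq_scale) * x1)
    return GaborKernel(weights=envelope * carrier, theta=theta, f=f, s=params.s)


def build_bank(params: GaborParams) -> GaborBank:
    """Build the full kernel bank, one kernel per (f, theta).

    With the default half-open [-90, 90) degree sweep in 1-degree steps
    this yields exactly 180 kernels per frequency factor.
    """
    kernels = [
        gabor_kernel(params, f, float(theta))
        for f in params.freqs
        for theta in params.thetas
    ]
    return GaborBank(kernels=tuple(kernels), params=params)


def _respond(pixels: np.ndarray, kernel: GaborKernel) -> np.ndarray:
    # Kernels are even-symmetric, so correlation equals convolution; use
    # correlate so the orientation convention matches the kernel grid as
    # written. 'reflect' replicates the edge sample (symmetric padding).
    return ndimage.correlate(pixels, kernel.weights, mode="reflect")


def apply_fgt(
    img: GrayImage,
    bank: GaborBank,
    per_frequency: bool = False,
) -> GrayImage | list[GrayImage]:
    """Convolve with every kernel and fuse by per-pixel maximum.

    Each kernel produces a same-size response map (reflective border);
    the fused image is the pointwise maximum over signed responses,
    min-max rescaled to [0, 1] (a constant fused map becomes all zeros).

    With ``per_frequency=True`` fusion runs separately over the
    orientations of each frequency factor and a list of fused images is
    returned, ordered like ``bank.params.freqs``.
    """
    if len(bank) == 0:
        raise ValueError("empty Gabor bank")
    ksize = 2 * bank.params.support_radius + 1
    if ksize > img.height or ksize > img.width:
        raise ValueError(
            f"kernel size {ksize} exceeds image {img.height}x{img.width}"
        )

    if per_frequency:
        n_th = bank.params.n_orientations
        out = []
        for i in range(len(bank.params.freqs)):
            group = bank.kernels[i * n_th : (i + 1) * n_th]
            fused = _fuse(img.pixels, group)
            out.append(GrayImage(fused, spacing_mm=img.spacing_mm))
        return out
    fused = _fuse(img.pixels, bank.kernels)
    return GrayImage(fused, spacing_mm=img.spacing_mm)


def _fuse(pixels: np.ndarray, kernels) -> np.ndarray:
    acc = _respond(pixels, kernels[0])
    for k in kernels[1:]:
        np.maximum(acc, _respond(pixels, k), out=acc)
    lo, hi = float(acc.min()), float(acc.max())
    if hi - lo == 0.0:
        return np.zeros_like(acc)
    return (acc - lo) / (hi - lo)
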