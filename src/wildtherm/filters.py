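"""Pixel-neighborhood operators used by the detection pipelines.

All windowed operators replicate edge pixels at the border (a frame border
padded with zeros would read as a spurious cold-to-warm step and create fake
edges).  Intermediate arithmetic is floating point; results are rounded
half-up back to 8-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ShapeError
from .imaging import GrayImage, as_gray, round_half_up

#: normalized 3x3 binomial kernel, the default Gaussian blur mask
BINOMIAL_3X3 = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=np.float64) / 16.0


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral filter parameters.

    diameter
        Full width of the square neighborhood Omega, in pixels (odd, >= 3).
    sigma_s
        Spatial Gaussian scale (pixels): closer neighbors weigh more.
    sigma_r
        Range Gaussian scale (intensity units): similar intensities weigh
        more, which is what preserves edges.
    """

    diameter: int = 9
    sigma_s: float = 75.0
    sigma_r: float = 75.0

    def __post_init__(self):
        if self.diameter % 2 == 0 or self.diameter < 3:
            raise ParameterError(f"diameter must be odd and >= 3, got {self.diameter}")
        if self.sigma_s <= 0 or self.sigma_r <= 0:
            raise ParameterError("sigma_s and sigma_r must be positive")


@dataclass(frozen=True)
class GaussianParams:
    """Gaussian blur mask of half-width k (mask size (2k+1) x (2k+1))."""

    k: int = 1
    kernel: np.ndarray = field(default_factory=lambda: BINOMIAL_3X3.copy())

    def __post_init__(self):
        kern = np.asarray(self.kernel, dtype=np.float64)
        n = 2 * self.k + 1
        if kern.shape != (n, n):
            raise ParameterError(f"kernel must be {n}x{n} for k={self.k}")
        if np.any(kern < 0) or abs(kern.sum() - 1.0) > 1e-12:
            raise ParameterError("kernel weights must be non-negative and sum to 1")
        if not np.allclose(kern, np.rot90(kern)):
            raise ParameterError("kernel must be symmetric under 90-degree rotation")
        object.__setattr__(self, "kernel", kern)


@dataclass(frozen=True)
class ThresholdParams:
    """Global binarization: strictly greater than `threshold` maps to i_max."""

    threshold: int = 180
    i_max: int = 255

    def __post_init__(self):
        if not 0 <= self.threshold < 256:
            raise ParameterError(f"threshold must be in [0, 255], got {self.threshold}")
        if not 1 <= self.i_max <= 255:
            raise ParameterError(f"i_max must be in [1, 255], got {self.i_max}")


@dataclass(frozen=True)
class DilationParams:
    """Flat square structuring element for grayscale dilation."""

    kernel_size: int = 5

    def __post_init__(self):
        if self.kernel_size % 2 == 0 or self.kernel_size < 3:
            raise ParameterError(
                f"kernel_size must be odd and >= 3, got {self.kernel_size}"
            )


def _padded(img: np.ndarray, radius: int) -> np.ndarray:
    return np.pad(img, radius, mode="edge")


def bilateral_filter(img: GrayImage, p: BilateralParams = BilateralParams()) -> GrayImage:
    """Edge-preserving smoothing.

    Each output pixel is the normalized sum of neighborhood intensities
    weighted by the product of a spatial Gaussian (Euclidean pixel distance,
    scale ``sigma_s``) and a range Gaussian (intensity difference to the
    center pixel, scale ``sigma_r``).
    """
    img = as_gray(img)
    r = p.diameter // 2
    src = _padded(img, r).astype(np.float64)
    center = img.astype(np.float64)
    h, w = img.shape
    num = np.zeros((h, w), dtype=np.float64)
    den = np.zeros((h, w), dtype=np.float64)
    inv2ss = 1.0 / (2.0 * p.sigma_s**2)
    inv2sr = 1.0 / (2.0 * p.sigma_r**2)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            shifted = src[r + dr : r + dr + h, r + dc : r + dc + w]
            ws = np.exp(-(dr * dr + dc * dc) * inv2ss)
            wr = np.exp(-((shifted - center) ** 2) * inv2sr)
            wgt = ws * wr
            num += wgt * shifted
            den += wgt
    return round_half_up(num / den).clip(0, 255).astype(np.uint8)


def gaussian_blur(img: GrayImage, p: GaussianParams = GaussianParams()) -> GrayImage:
    """2-D convolution with a normalized Gaussian mask, edge-replicated."""
    img = as_gray(img)
    k = p.k
    src = _padded(img, k).astype(np.float64)
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.float64)
    # the mask is rotation-symmetric, so convolution equals correlation
    for dr in range(-k, k + 1):
        for dc in range(-k, k + 1):
            out += p.kernel[dr + k, dc + k] * src[k + dr : k + dr + h, k + dc : k + dc + w]
    return round_half_up(out).clip(0, 255).astype(np.uint8)


def threshold(img: GrayImage, p: ThresholdParams = ThresholdParams()) -> GrayImage:
    """Binarize: intensities strictly above the threshold become ``i_max``."""
    img = as_gray(img)
    return np.where(img > p.threshold, p.i_max, 0).astype(np.uint8)


def dilate(img: GrayImage, p: DilationParams = DilationParams()) -> GrayImage:
    """Grayscale dilation: sliding-window maximum over a flat square kernel."""
    img = as_gray(img)
    r = p.kernel_size // 2
    src = _padded(img, r)
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            np.maximum(out, src[r + dr : r + dr + h, r + dc : r + dc + w], out=out)
    return out


def abs_difference(prev: GrayImage, curr: GrayImage) -> GrayImage:
    """Per-pixel absolute difference of two equally sized frames."""
    prev, curr = as_gray(prev), as_gray(curr)
    if prev.shape != curr.shape:
        raise ShapeError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    a = prev.astype(np.int16)
    b = curr.astype(np.int16)
    return np.abs(a - b).astype(np.uint8)
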