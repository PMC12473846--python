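"""Sobel gradients and the Canny chain: thinning, double threshold, hysteresis.

The gradient direction is quantized to the four orientations 0/45/90/135
degrees (modulo 180): 0 means a horizontal gradient (vertical edge).
Magnitudes stay real-valued until hysteresis produces the binary edge map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .imaging import GrayImage, as_gray

SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_GY = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)

_ORIENTATIONS = np.array([0, 45, 90, 135])
# pixel offsets of the positive-direction neighbor for each orientation;
# (row, col) with row increasing downward, so 45 deg steps up-and-right
_DIR_STEP = {0: (0, 1), 45: (-1, 1), 90: (1, 0), 135: (1, 1)}

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient magnitude and quantized direction."""

    magnitude: np.ndarray  # float64, >= 0
    direction: np.ndarray  # int, values in {0, 45, 90, 135}

    def __post_init__(self):
        if self.magnitude.shape != self.direction.shape:
            raise ParameterError("magnitude and direction shapes differ")


@dataclass(frozen=True)
class CannyParams:
    """Double-threshold levels on the Sobel magnitude scale."""

    low_threshold: float = 50.0
    high_threshold: float = 100.0

    def __post_init__(self):
        if not 0 <= self.low_threshold <= self.high_threshold:
            raise ParameterError("need 0 <= low_threshold <= high_threshold")


def _correlate3(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    src = np.pad(img, 1, mode="edge").astype(np.float64)
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.float64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            out += mask[dr + 1, dc + 1] * src[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    return out


def quantize_direction(theta_deg: np.ndarray) -> np.ndarray:
    """Map raw angles to the nearest of {0, 45, 90, 135} mod 180.

    Ties (angles exactly halfway between two orientations) go to the smaller
    orientation label.
    """
    t = np.mod(np.asarray(theta_deg, dtype=np.float64), 180.0)
    d = np.abs(t[..., None] - _ORIENTATIONS[None, :])
    d = np.minimum(d, 180.0 - d)  # circular distance mod 180
    # argmin scans labels in increasing order, so exact ties pick the smaller
    return _ORIENTATIONS[np.argmin(np.round(d, 9), axis=-1)]


def sobel_gradients(img: GrayImage) -> GradientField:
    """Gradient magnitude sqrt(Gx^2+Gy^2) and quantized direction."""
    img = as_gray(img).astype(np.float64)
    gx = _correlate3(img, SOBEL_GX)
    gy = _correlate3(img, SOBEL_GY)
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx))
    return GradientField(magnitude=mag, direction=quantize_direction(theta))


def non_max_suppression(gf: GradientField) -> GradientField:
    """Edge thinning: keep a pixel only if it is a local maximum (ties kept)
    along its quantized gradient direction; out-of-bounds neighbors count 0.
    """
    mag, dirs = gf.magnitude, gf.direction
    h, w = mag.shape
    out = np.zeros_like(mag)
    for ori, (dr, dc) in _DIR_STEP.items():
        sel = dirs == ori
        if not np.any(sel):
            continue
        fwd = np.zeros_like(mag)
        bwd = np.zeros_like(mag)
        # neighbor magnitudes shifted into place; borders stay 0
        fwd[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)] = mag[
            max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)
        ]
        bwd[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)] = mag[
            max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)
        ]
        keep = sel & (mag >= fwd) & (mag >= bwd)
        out[keep] = mag[keep]
    return GradientField(magnitude=out, direction=dirs.copy())


def hysteresis(gf: GradientField, p: CannyParams = CannyParams()) -> GrayImage:
    """Double thresholding with 8-connected weak-to-strong edge linking.

    Strong pixels (magnitude > high) are edges; weak pixels
    (low < magnitude <= high) survive only when 8-connected to a strong pixel
    through chains of strong/weak pixels.
    """
    mag = gf.magnitude
    strong = mag > p.high_threshold
    candidate = mag > p.low_threshold  # strong or weak
    labels, n = ndimage.label(candidate, structure=_EIGHT)
    if n == 0:
        return np.zeros(mag.shape, dtype=np.uint8)
    has_strong = np.zeros(n + 1, dtype=bool)
    has_strong[np.unique(labels[strong])] = True
    has_strong[0] = False
    edge = has_strong[labels]
    return np.where(edge, 255, 0).astype(np.uint8)


def canny(img: GrayImage, p: CannyParams = CannyParams()) -> GrayImage:
    """Full edge chain: Sobel -> non-maximum suppression -> hysteresis.

    The caller is expected to Gaussian-blur the frame first (the pipeline
    does); this function performs no smoothing of its own.
    """
    return hysteresis(non_max_suppression(sobel_gradients(img)), p)
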