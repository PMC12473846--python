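"""Nearest-average (k-means) intensity quantization.

Pixel intensities are clustered into ``k`` groups by Lloyd iteration:
assign every pixel to the nearest center (squared intensity distance, ties
to the lower-indexed center), then move each center to the mean of its
group, until no center moves more than ``epsilon`` or the iteration budget
is exhausted.  The quantized image replaces every pixel with its rounded
cluster center, so it carries at most ``k`` distinct gray levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .imaging import GrayImage, as_gray, round_half_up


@dataclass(frozen=True)
class QuantizationParams:
    k: int = 2
    max_iterations: int = 200
    epsilon: float = 0.5  # stop when max center movement <= epsilon
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.epsilon < 0:
            raise ParameterError("epsilon must be >= 0")


@dataclass
class ClusterState:
    """Converged cluster centers, per-pixel assignments and iteration trace."""

    centers: np.ndarray  # float64, shape (k,)
    assignments: np.ndarray  # int, same shape as the image
    iterations_run: int
    objective_trace: list[float] = field(default_factory=list)


def _assign(flat: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = (flat[:, None] - centers[None, :]) ** 2
    return np.argmin(d2, axis=1)  # first minimum -> lower-indexed center


def kmeans_quantize(
    img: GrayImage, p: QuantizationParams = QuantizationParams()
) -> tuple[GrayImage, ClusterState]:
    """Quantize an image to ``k`` gray levels by 1-D k-means.

    Initialization draws ``k`` distinct pixel values uniformly at random with
    the configured seed; when the image has fewer than ``k`` distinct values
    the surplus centers duplicate existing values and collapse onto them.
    An empty cluster is re-seeded on the pixel value farthest from its
    current center.
    """
    img = as_gray(img)
    flat = img.ravel().astype(np.float64)
    if p.k > flat.size:
        raise ParameterError(f"k={p.k} exceeds pixel count {flat.size}")
    rng = np.random.default_rng(p.seed)
    distinct = np.unique(flat)
    if distinct.size >= p.k:
        centers = rng.choice(distinct, size=p.k, replace=False).astype(np.float64)
    else:
        centers = rng.choice(distinct, size=p.k, replace=True).astype(np.float64)

    assignments = _assign(flat, centers)
    trace: list[float] = []
    iterations = 0
    for iterations in range(1, p.max_iterations + 1):
        new_centers = centers.copy()
        for i in range(p.k):
            members = flat[assignments == i]
            if members.size:
                new_centers[i] = members.mean()
            else:
                new_centers[i] = flat[np.argmax(np.abs(flat - centers[i]))]
        movement = np.max(np.abs(new_centers - centers))
        centers = new_centers
        assignments = _assign(flat, centers)
        trace.append(float(np.sum((flat - centers[assignments]) ** 2)))
        if movement <= p.epsilon:
            break

    state = ClusterState(
        centers=centers,
        assignments=assignments.reshape(img.shape),
        iterations_run=iterations,
        objective_trace=trace,
    )
    levels = round_half_up(centers).clip(0, 255).astype(np.uint8)
    return levels[state.assignments], state


def quantized_to_binary(img: GrayImage, state: ClusterState) -> GrayImage:
    """Map the brighter of two clusters to white (255), the darker to black.

    Thermal imagery renders warm bodies as the lightest shades, so the
    brighter cluster is the candidate-object class.
    """
    if state.centers.size != 2:
        raise ParameterError(
            f"binary mapping needs exactly 2 clusters, got {state.centers.size}"
        )
    c0, c1 = state.centers
    if c0 == c1:
        warnings.warn(
            "degenerate quantization: both cluster centers are equal; "
            "emitting an all-black image",
            stacklevel=2,
        )
        return np.zeros(state.assignments.shape, dtype=np.uint8)
    bright = int(c1 > c0)
    return np.where(state.assignments == bright, 255, 0).astype(np.uint8)
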