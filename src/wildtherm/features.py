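"""Keypoint features and the contour-matching animal decision.

The detector is a compact scale-invariant feature pipeline: difference-of-
Gaussians extrema over an octave pyramid, low-contrast and edge-response
rejection, dominant gradient orientation, and a 4x4x8 orientation-histogram
descriptor (128-dim, L2-normalized).  Matching is exhaustive nearest-neighbor
search under Euclidean descriptor distance with Lowe's ratio test.  A frame
is declared to contain an animal when some interior contour's features match
a reference chip of a known animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, ParameterError
from .imaging import BBox, GrayImage, as_gray
from .contours import Contour

_CONTRAST_THRESH = 0.03  # on [0, 1] intensity scale
_EDGE_RATIO = 10.0
_N_INTERVALS = 3
_SIGMA0 = 1.6
_MAX_KEYPOINTS = 200
_DESC_WIDTH = 4
_DESC_BINS = 8


@dataclass(frozen=True)
class Keypoint:
    row: float
    col: float
    sigma: float
    orientation_deg: float


@dataclass(frozen=True)
class FeatureSet:
    keypoints: tuple[Keypoint, ...]
    descriptors: np.ndarray  # shape (n, 128), float64

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass(frozen=True)
class ReferenceChip:
    """Cropped image of a known animal with its cached feature set."""

    image: GrayImage
    label: str
    features: FeatureSet = field(init=False)

    def __post_init__(self):
        img = as_gray(self.image)
        if img.shape[0] < 8 or img.shape[1] < 8:
            raise ParameterError(
                f"chip {self.label!r} must be at least 8x8, got {img.shape}"
            )
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "features", detect_features(img))


@dataclass(frozen=True)
class MatchDecisionParams:
    """Decision thresholds for the feature-matching stage.

    ``fallback_area`` enables an area-only candidate rule for targets too
    small to carry any descriptor (a distant moose spans only a few pixels);
    it is off by default so the decision stays purely feature-based.
    """

    min_good_matches: int = 4
    ratio: float = 0.75
    min_contour_area: int = 9
    fallback_area: int | None = None

    def __post_init__(self):
        if self.min_good_matches < 1:
            raise ParameterError("min_good_matches must be >= 1")
        if not 0 < self.ratio <= 1:
            raise ParameterError("ratio must be in (0, 1]")


def _gaussian_pyramid(img: np.ndarray):
    """Per-octave Gaussian stacks and their difference-of-Gaussian stacks.

    The first octave works on a 2x-upsampled copy of the image so that
    blobs only a few pixels across still produce an interior scale-space
    extremum (their response peaks below the base sigma otherwise).
    """
    base = ndimage.zoom(img, 2, order=1)
    n_oct = max(1, min(3, int(np.log2(max(1, min(base.shape) // 8))) + 1))
    k = 2.0 ** (1.0 / _N_INTERVALS)
    octaves, dogs, sigmas = [], [], []
    for o in range(n_oct):
        stack = [ndimage.gaussian_filter(base, _SIGMA0)]
        sig = [_SIGMA0]
        for i in range(1, _N_INTERVALS + 3):
            s_total = _SIGMA0 * k**i
            s_inc = np.sqrt(s_total**2 - sig[-1] ** 2)
            stack.append(ndimage.gaussian_filter(stack[-1], s_inc))
            sig.append(s_total)
        stack = np.stack(stack)
        octaves.append(stack)
        dogs.append(stack[1:] - stack[:-1])
        sigmas.append(sig)
        base = stack[_N_INTERVALS][::2, ::2]
        if min(base.shape) < 8:
            n_oct = o + 1
            break
    return octaves, dogs, sigmas


def _is_extremum(dog: np.ndarray, layer: int, r: int, c: int) -> bool:
    cube = dog[layer - 1 : layer + 2, r - 1 : r + 2, c - 1 : c + 2]
    v = dog[layer, r, c]
    if v > 0:
        return v >= cube.max() and (cube == v).sum() == 1
    return v <= cube.min() and (cube == v).sum() == 1


def _passes_edge_test(d: np.ndarray, r: int, c: int) -> bool:
    dxx = d[r, c + 1] + d[r, c - 1] - 2 * d[r, c]
    dyy = d[r + 1, c] + d[r - 1, c] - 2 * d[r, c]
    dxy = (d[r + 1, c + 1] - d[r + 1, c - 1] - d[r - 1, c + 1] + d[r - 1, c - 1]) / 4.0
    tr, det = dxx + dyy, dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    return tr * tr / det < (_EDGE_RATIO + 1) ** 2 / _EDGE_RATIO


def _gradients(img: np.ndarray):
    gr = np.zeros_like(img)
    gc = np.zeros_like(img)
    gr[1:-1, :] = (img[2:, :] - img[:-2, :]) / 2.0
    gc[:, 1:-1] = (img[:, 2:] - img[:, :-2]) / 2.0
    return np.hypot(gr, gc), np.degrees(np.arctan2(gr, gc)) % 360.0


def _dominant_orientation(mag, ang, r, c, sigma) -> float:
    radius = max(2, int(round(3 * 1.5 * sigma)))
    h, w = mag.shape
    r0, r1 = max(0, r - radius), min(h, r + radius + 1)
    c0, c1 = max(0, c - radius), min(w, c + radius + 1)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    weight = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * (1.5 * sigma) ** 2))
    hist = np.zeros(36)
    bins = (ang[r0:r1, c0:c1] // 10).astype(int) % 36
    np.add.at(hist, bins.ravel(), (weight * mag[r0:r1, c0:c1]).ravel())
    return float(np.argmax(hist) * 10.0 + 5.0)


def _descriptor(mag, ang, r, c, sigma, orientation) -> np.ndarray:
    """4x4 spatial grid x 8 orientation bins over a rotated 16x16 sample patch."""
    h, w = mag.shape
    desc = np.zeros((_DESC_WIDTH, _DESC_WIDTH, _DESC_BINS))
    theta = np.radians(orientation)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    step = max(0.75, 0.75 * sigma)  # sample spacing scales with keypoint size
    half = _DESC_WIDTH * 2  # 8 samples per side
    for i in range(-half, half):
        for j in range(-half, half):
            u, v = (i + 0.5) * step, (j + 0.5) * step
            dr = u * cos_t - v * sin_t
            dc = u * sin_t + v * cos_t
            rr, cc = int(round(r + dr)), int(round(c + dc))
            if not (0 <= rr < h and 0 <= cc < w):
                continue
            cell_r = (i + half) // _DESC_WIDTH
            cell_c = (j + half) // _DESC_WIDTH
            rel = (ang[rr, cc] - orientation) % 360.0
            b = int(rel // (360.0 / _DESC_BINS)) % _DESC_BINS
            wgt = np.exp(-(u * u + v * v) / (2 * (half * step) ** 2))
            desc[cell_r, cell_c, b] += wgt * mag[rr, cc]
    vec = desc.ravel()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = np.minimum(vec / norm, 0.2)
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec = vec / norm
    return vec


def detect_features(img: GrayImage, region: BBox | None = None) -> FeatureSet:
    """Detect scale-space keypoints and descriptors in a region of the image.

    Regions smaller than 64 px yield an empty feature set with a warning
    (there is nothing a descriptor could latch onto at that size).
    """
    img = as_gray(img)
    if region is not None:
        r0, c0, r1, c1 = region
        if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
            raise ParameterError(f"region {region} outside image {img.shape}")
        img = img[r0:r1, c0:c1]
        offset = (r0, c0)
    else:
        offset = (0, 0)
    if img.size < 64:
        warnings.warn(
            f"region of {img.size} px is below the 64-px feature minimum; "
            "returning an empty feature set",
            stacklevel=2,
        )
        return FeatureSet(keypoints=(), descriptors=np.empty((0, 128)))

    f = img.astype(np.float64) / 255.0
    octaves, dogs, sigmas = _gaussian_pyramid(f)
    raw: list[tuple[float, Keypoint, np.ndarray]] = []
    for o, dog in enumerate(dogs):
        grads = {}
        for layer in range(1, _N_INTERVALS + 1):
            d = dog[layer]
            h, w = d.shape
            if h < 3 or w < 3:
                continue
            cand = np.abs(d) > _CONTRAST_THRESH
            cand[0, :] = cand[-1, :] = cand[:, 0] = cand[:, -1] = False
            for r, c in zip(*np.nonzero(cand)):
                if not _is_extremum(dog, layer, r, c):
                    continue
                if not _passes_edge_test(d, r, c):
                    continue
                if layer not in grads:
                    grads[layer] = _gradients(octaves[o][layer])
                mag, ang = grads[layer]
                sigma = sigmas[o][layer]
                ori = _dominant_orientation(mag, ang, r, c, sigma)
                vec = _descriptor(mag, ang, r, c, sigma, ori)
                if not np.any(vec):
                    continue
                scale = 2.0 ** (o - 1)  # octave 0 is the upsampled image
                kp = Keypoint(
                    row=offset[0] + r * scale,
                    col=offset[1] + c * scale,
                    sigma=sigma * scale,
                    orientation_deg=ori,
                )
                raw.append((abs(float(d[r, c])), kp, vec))
    raw.sort(key=lambda t: (-t[0], t[1].row, t[1].col, t[1].sigma))
    raw = raw[:_MAX_KEYPOINTS]
    if not raw:
        return FeatureSet(keypoints=(), descriptors=np.empty((0, 128)))
    return FeatureSet(
        keypoints=tuple(kp for _, kp, _ in raw),
        descriptors=np.stack([v for _, _, v in raw]),
    )


def match_features(
    query: FeatureSet, ref: FeatureSet, p: MatchDecisionParams = MatchDecisionParams()
) -> int:
    """Count good matches by exhaustive nearest-neighbor descriptor search.

    A query feature is a good match when its nearest reference descriptor is
    closer than ``ratio`` times the second nearest (Lowe's test); an exact
    match (distance 0) or a missing second neighbor always qualifies.
    """
    if len(query) == 0 or len(ref) == 0:
        return 0
    d = cdist(query.descriptors, ref.descriptors)
    good = 0
    for i in range(d.shape[0]):
        row = np.sort(d[i])
        if row.size == 1 or row[0] == 0.0 or row[0] < p.ratio * row[1]:
            good += 1
    return good


def decide_animal(
    img: GrayImage,
    contours: list[Contour],
    library: list[ReferenceChip],
    p: MatchDecisionParams = MatchDecisionParams(),
) -> tuple[bool, list[tuple[Contour, str, int]]]:
    """Decide whether any contour region matches a known-animal chip.

    Contours smaller than ``min_contour_area`` are skipped.  A contour scores
    a hit when its bounding-box features reach ``min_good_matches`` against
    some chip, or (when enabled) its area reaches ``fallback_area``.
    Returns the presence flag and all qualifying (contour, label, count) hits.
    """
    if not library:
        raise ConfigurationError("reference chip library is empty")
    img = as_gray(img)
    hits: list[tuple[Contour, str, int]] = []
    for ct in contours:
        if ct.area_px < p.min_contour_area:
            continue
        r0, c0, r1, c1 = ct.bbox
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny regions are expected here
            query = detect_features(img, region=(r0, c0, r1, c1))
        best_label, best_count = None, 0
        for chip in library:
            count = match_features(query, chip.features, p)
            if count > best_count:
                best_label, best_count = chip.label, count
        if best_count >= p.min_good_matches:
            hits.append((ct, best_label, best_count))
        elif p.fallback_area is not None and ct.area_px >= p.fallback_area:
            hits.append((ct, "area-fallback", best_count))
    return bool(hits), hits
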