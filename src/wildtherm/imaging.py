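"""Image data model, frame I/O and region-of-interest cropping.

Grayscale frames are plain ``numpy.uint8`` arrays indexed ``(row, col)`` with
the origin at the top-left corner.  Bounding boxes are half-open
``(r0, c0, r1, c1)`` tuples.  The ROI is a simple polygon in the same
coordinate system; cropping keeps the polygon's tight bounding box and zeroes
every pixel outside the polygon, which removes warm road/sky interference
while leaving the roadside grassland intact.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from PIL import Image, UnidentifiedImageError
from shapely.geometry import Polygon

from .errors import (
    AmbiguityError,
    BoundsError,
    EmptyInputError,
    FormatError,
    ParameterError,
)

GrayImage = np.ndarray  # uint8, shape (H, W)
BBox = tuple[int, int, int, int]  # half-open (r0, c0, r1, c1)

_FRAME_SUFFIXES = (".png", ".pgm")
_NAME_EPOCH_RE = re.compile(r"^(?P<id>.+)_(?P<epoch>\d+)$")


def as_gray(pixels) -> GrayImage:
    """Validate and coerce an array-like into a uint8 grayscale image."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ParameterError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ParameterError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 going up (not banker's rounding)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def read_frame(path) -> GrayImage:
    """Read an 8-bit grayscale PNG or PGM frame.

    Color images are converted by the per-pixel channel average, rounded
    half-up.  Bit depths other than 8 raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("RGB", "RGBA"):
                rgb = np.asarray(im)[..., :3].astype(np.float64)
                return round_half_up(rgb.mean(axis=2)).astype(np.uint8)
            if mode == "L":
                return np.asarray(im, dtype=np.uint8)
            if mode in ("I", "I;16", "I;16B", "I;16L", "F"):
                raise FormatError(
                    f"{path.name}: 16/32-bit depth (mode {mode!r}) is unsupported; "
                    "frames must be 8-bit grayscale"
                )
            if mode == "P" or mode == "1":
                return np.asarray(im.convert("L"), dtype=np.uint8)
            raise FormatError(f"{path.name}: unsupported image mode {mode!r}")
    except UnidentifiedImageError as exc:
        raise OSError(f"cannot read image file {path}") from exc


def write_frame(path, img: GrayImage) -> None:
    """Write an 8-bit grayscale frame as PNG or PGM (by file extension)."""
    img = as_gray(img)
    Image.fromarray(img, mode="L").save(Path(path))


@dataclass(frozen=True)
class RoiPolygon:
    """Simple (non-self-intersecting) polygon in (row, col) coordinates.

    A pixel belongs to the ROI when its center lies inside the polygon or on
    its boundary.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if len(verts) < 3:
            raise ParameterError("polygon needs at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise ParameterError("polygon must be simple with non-zero area")
        object.__setattr__(self, "vertices", verts)

    @property
    def _shape(self) -> Polygon:
        return Polygon(self.vertices)

    def bbox(self) -> BBox:
        """Tight half-open pixel bounding box of the polygon."""
        rs = [v[0] for v in self.vertices]
        cs = [v[1] for v in self.vertices]
        import math

        r0, c0 = math.floor(min(rs)), math.floor(min(cs))
        r1, c1 = math.floor(max(rs)) + 1, math.floor(max(cs)) + 1
        return (r0, c0, r1, c1)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean in-ROI mask for an image of the given (H, W) shape."""
        h, w = shape
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        # shapely points take (x, y); the pairing is symmetric as long as the
        # polygon is built with the same (row->x, col->y) convention.
        pts = shapely.points(rr.ravel().astype(float), cc.ravel().astype(float))
        inside = shapely.covers(self._shape, pts)
        return inside.reshape(h, w)


def crop_roi(img: GrayImage, roi: RoiPolygon) -> GrayImage:
    """Crop to the ROI polygon's bounding box, zeroing out-of-polygon pixels.

    Zero is the coldest intensity, so masked-out road/sky pixels can never
    register as warm bodies downstream.
    """
    img = as_gray(img)
    h, w = img.shape
    r0, c0, r1, c1 = roi.bbox()
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise BoundsError(
            f"ROI bbox ({r0},{c0},{r1},{c1}) exceeds image bounds {h}x{w}"
        )
    mask = roi.mask(img.shape)
    out = np.where(mask, img, 0).astype(np.uint8)
    return out[r0:r1, c0:c1]


@dataclass
class FrameSequence:
    """Time-ordered grayscale frames with stable string identifiers."""

    frames: list[GrayImage]
    timestamps: list[float]
    frame_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.frames) == len(self.timestamps) == len(self.frame_ids)):
            raise ParameterError("frames, timestamps and frame_ids must align")
        ts = np.asarray(self.timestamps, dtype=float)
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ParameterError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def _parse_manifest(manifest) -> dict[str, float]:
    times: dict[str, float] = {}
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            times[row["frame_id"]] = float(row["timestamp_s"])
    return times


def load_sequence(directory, manifest=None) -> FrameSequence:
    """Load all PNG/PGM frames in a directory, ordered by timestamp.

    Timestamps come from the manifest CSV (``frame_id,timestamp_s``) when
    given, otherwise from ``<id>_<epoch-seconds>`` filename stems.  Ties are
    broken by filename lexicographic order; identical timestamps on identical
    filenames cannot occur, so ordering is always deterministic.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not paths:
        raise EmptyInputError(f"no readable frames in {directory}")

    times = _parse_manifest(manifest) if manifest is not None else None
    entries = []
    for p in paths:
        stem = p.stem
        if times is not None:
            if stem in times:
                fid, ts = stem, times[stem]
            else:
                m = _NAME_EPOCH_RE.match(stem)
                fid = m.group("id") if m else stem
                if fid not in times:
                    raise AmbiguityError(f"manifest has no timestamp for {p.name}")
                ts = times[fid]
        else:
            m = _NAME_EPOCH_RE.match(stem)
            if not m:
                raise AmbiguityError(
                    f"cannot parse epoch from {p.name}; expected <id>_<epoch> "
                    "or provide a manifest"
                )
            fid, ts = m.group("id"), float(m.group("epoch"))
        entries.append((ts, p.name, fid, p))

    entries.sort(key=lambda e: (e[0], e[1]))
    seen: dict[float, str] = {}
    for ts, name, _, _ in entries:
        if ts in seen and seen[ts] == name:
            raise AmbiguityError(f"duplicate timestamp {ts} without distinct names")
        seen[ts] = name

    frames = [read_frame(p) for _, _, _, p in entries]
    # strictly-increasing invariant: nudge exact ties by filename order
    ts_list: list[float] = []
    for ts, _, _, _ in entries:
        if ts_list and ts <= ts_list[-1]:
            ts = np.nextafter(ts_list[-1], np.inf)
        ts_list.append(float(ts))
    return FrameSequence(
        frames=frames,
        timestamps=ts_list,
        frame_ids=[fid for _, _, fid, _ in entries],
    )
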