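"""The four end-to-end detection pipelines and the boundary-event classifier.

Every pipeline ends in the same decision stage: extract contours from a
binary image, reject those intersecting the frame edge (objects partially
outside the field of view), and test the surviving contour regions against
the reference chip library.  Border-touching contours are still evaluated
separately so the boundary-event classifier can reason about animals
entering or leaving the monitored area, even though they never trigger a
detection on their own.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from enum import Enum

from .config import PipelineConfig
from .contours import find_contours, reject_border_contours
from .errors import EmptyInputError, ParameterError, ShapeError
from .features import decide_animal
from .filters import abs_difference, bilateral_filter, dilate, gaussian_blur, threshold
from .edges import canny
from .imaging import BBox, FrameSequence, GrayImage
from .quantize import kmeans_quantize, quantized_to_binary
from .filters import ThresholdParams

log = logging.getLogger("wildtherm")

METHODS = ("bilateral", "canny", "quantize", "motion")


@dataclass
class DetectionResult:
    frame_id: str
    present: bool
    boxes: list[BBox]
    elapsed_s: float
    method: str
    border_present: bool = False  # a border-touching contour matched
    scored: bool = True  # False for a motion run's first frame
    n_contours: int = 0
    n_matches: int = 0


class EventKind(str, Enum):
    ENTERED = "ENTERED"
    EXITING = "EXITING"
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"


@dataclass(frozen=True)
class BoundaryEvent:
    frame_id: str
    kind: EventKind


def _decision_stage(
    binary: GrayImage, frame: GrayImage, cfg: PipelineConfig, frame_id: str, method: str
) -> DetectionResult:
    contours = find_contours(binary)
    interior = reject_border_contours(contours)
    present, hits = decide_animal(frame, interior, cfg.library, cfg.match)
    border = [c for c in contours if c.touches_border]
    border_present, _ = decide_animal(frame, border, cfg.library, cfg.match)
    boxes = [h[0].bbox for h in hits]
    return DetectionResult(
        frame_id=frame_id,
        present=present,
        boxes=boxes,
        elapsed_s=0.0,
        method=method,
        border_present=border_present,
        n_contours=len(contours),
        n_matches=max((h[2] for h in hits), default=0),
    )


def _notify(res: DetectionResult) -> None:
    if res.present:
        log.info(
            "notification: animal detected frame=%s method=%s contours=%d "
            "matches=%d elapsed=%.4fs",
            res.frame_id, res.method, res.n_contours, res.n_matches, res.elapsed_s,
        )


def run_bilateral_pipeline(
    frame: GrayImage, cfg: PipelineConfig, frame_id: str = "frame"
) -> DetectionResult:
    """Bilateral smoothing, global thresholding, contour matching."""
    t0 = time.perf_counter()
    binary = threshold(bilateral_filter(frame, cfg.bilateral), cfg.threshold)
    res = _decision_stage(binary, frame, cfg, frame_id, "bilateral")
    res.elapsed_s = time.perf_counter() - t0
    _notify(res)
    return res


def run_canny_pipeline(
    frame: GrayImage, cfg: PipelineConfig, frame_id: str = "frame"
) -> DetectionResult:
    """Gaussian blur, Canny edge map, contour matching."""
    t0 = time.perf_counter()
    binary = canny(gaussian_blur(frame, cfg.gaussian), cfg.canny)
    res = _decision_stage(binary, frame, cfg, frame_id, "canny")
    res.elapsed_s = time.perf_counter() - t0
    _notify(res)
    return res


def run_quantize_pipeline(
    frame: GrayImage, cfg: PipelineConfig, frame_id: str = "frame"
) -> DetectionResult:
    """Gaussian blur, two-level k-means quantization, contour matching."""
    t0 = time.perf_counter()
    blurred = gaussian_blur(frame, cfg.gaussian)
    _, state = kmeans_quantize(blurred, cfg.quantize)
    binary = quantized_to_binary(blurred, state)
    res = _decision_stage(binary, frame, cfg, frame_id, "quantize")
    res.elapsed_s = time.perf_counter() - t0
    _notify(res)
    return res


def run_motion_pipeline(
    prev: GrayImage, curr: GrayImage, cfg: PipelineConfig, frame_id: str = "frame"
) -> DetectionResult:
    """Frame differencing: blur both frames, absolute difference, dilation,
    thresholding, contour matching on the current frame."""
    if prev.shape != curr.shape:
        raise ShapeError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    t0 = time.perf_counter()
    diff = abs_difference(gaussian_blur(prev, cfg.gaussian), gaussian_blur(curr, cfg.gaussian))
    binary = threshold(
        dilate(diff, cfg.dilation),
        ThresholdParams(threshold=cfg.motion_threshold, i_max=cfg.threshold.i_max),
    )
    res = _decision_stage(binary, curr, cfg, frame_id, "motion")
    res.elapsed_s = time.perf_counter() - t0
    _notify(res)
    return res


def classify_boundary_events(history: list[DetectionResult]) -> list[BoundaryEvent]:
    """Classify each frame of a detection history.

    ENTERED: a border-touching detection with no detection in the previous
    frame (the animal just came into view).  EXITING: a border-touching
    detection following an earlier detection (the animal is leaving; no
    threat notification is raised).  PRESENT: an interior detection.
    ABSENT: no detection.
    """
    events: list[BoundaryEvent] = []
    prev_detected = False
    for res in history:
        if res.border_present and not prev_detected:
            kind = EventKind.ENTERED
        elif res.border_present and prev_detected:
            kind = EventKind.EXITING
        elif res.present:
            kind = EventKind.PRESENT
        else:
            kind = EventKind.ABSENT
        events.append(BoundaryEvent(frame_id=res.frame_id, kind=kind))
        prev_detected = res.present or res.border_present
    return events


_SINGLE_FRAME = {
    "bilateral": run_bilateral_pipeline,
    "canny": run_canny_pipeline,
    "quantize": run_quantize_pipeline,
}


def run_sequence(
    seq: FrameSequence, method: str, cfg: PipelineConfig
) -> list[DetectionResult]:
    """Run one method over a whole sequence, one result per frame.

    The motion method pairs each frame with its predecessor; frame 0 has no
    predecessor and is reported absent with ``scored=False`` so evaluation
    can exclude it from the confusion counts.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")
    if len(seq) == 0:
        raise EmptyInputError("empty frame sequence")
    if method == "motion":
        if len(seq) < 2:
            raise EmptyInputError("motion method needs at least 2 frames")
        results = [
            DetectionResult(
                frame_id=seq.frame_ids[0], present=False, boxes=[], elapsed_s=0.0,
                method="motion", scored=False,
            )
        ]
        for i in range(1, len(seq)):
            results.append(
                run_motion_pipeline(
                    seq.frames[i - 1], seq.frames[i], cfg, frame_id=seq.frame_ids[i]
                )
            )
        return results
    runner = _SINGLE_FRAME[method]
    return [
        runner(seq.frames[i], cfg, frame_id=seq.frame_ids[i]) for i in range(len(seq))
    ]
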