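import numpy as np
import pytest

from wildtherm.config import PipelineConfig
from wildtherm.errors import EmptyInputError, ParameterError, ShapeError
from wildtherm.filters import abs_difference
from wildtherm.imaging import FrameSequence
from wildtherm.pipelines import (
    DetectionResult,
    EventKind,
    classify_boundary_events,
    run_bilateral_pipeline,
    run_canny_pipeline,
    run_motion_pipeline,
    run_quantize_pipeline,
    run_sequence,
)

from conftest import animal_template, template_chip


def iou(a, b):
    r0, c0 = max(a[0], b[0]), max(a[1], b[1])
    r1, c1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    area = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / area if area else 0.0


@pytest.fixture()
def cfg():
    # benchmark-style decision config: the area fallback is on because the
    # pipelines fragment or smooth small targets below descriptor scale
    from wildtherm.features import MatchDecisionParams

    c = PipelineConfig()
    c.library = [template_chip()]
    c.match = MatchDecisionParams(fallback_area=9)
    return c


def animal_frame(intensity_cap=255, noise=3.0, seed=5, pos=(30, 40)):
    rng = np.random.default_rng(seed)
    frame = np.full((100, 120), 60.0)
    tmpl = np.minimum(animal_template(), intensity_cap)
    r, c = pos
    frame[r : r + 26, c : c + 22] = tmpl
    frame = frame + rng.normal(0, noise, frame.shape)
    return np.clip(np.round(frame), 0, 255).astype(np.uint8), (r + 3, c + 3, r + 24, c + 20)


class TestSingleFramePipelines:
    def test_blank_frame_absent_everywhere(self, cfg):
        blank = np.zeros((60, 80), dtype=np.uint8)
        assert not run_bilateral_pipeline(blank, cfg).present
        assert not run_canny_pipeline(blank, cfg).present
        with pytest.warns(UserWarning):
            assert not run_quantize_pipeline(blank, cfg).present

    def test_bilateral_detects_warm_animal_with_overlapping_box(self, cfg):
        frame, truth_box = animal_frame()
        res = run_bilateral_pipeline(frame, cfg)
        assert res.present and res.method == "bilateral"
        assert max(iou(b, truth_box) for b in res.boxes) >= 0.3

    def test_bilateral_misses_blob_below_threshold(self, cfg):
        frame, _ = animal_frame(intensity_cap=150)
        assert not run_bilateral_pipeline(frame, cfg).present

    def test_canny_detects_warm_animal(self, cfg):
        frame, truth_box = animal_frame()
        res = run_canny_pipeline(frame, cfg)
        assert res.present
        # edge rings fragment, so require overlap rather than high IoU
        assert any(iou(b, truth_box) > 0 for b in res.boxes)

    def test_canny_border_touching_region_rejected(self, cfg):
        frame = np.full((60, 80), 40, dtype=np.uint8)
        frame[0:20, 30:50] = 220  # warm region touching the top edge
        res = run_canny_pipeline(frame, cfg)
        assert not res.present
        assert res.border_present or res.n_contours > 0

    def test_quantize_isolates_bimodal_blob(self, cfg):
        frame, truth_box = animal_frame(noise=2.0)
        res = run_quantize_pipeline(frame, cfg)
        assert res.present
        assert max(iou(b, truth_box) for b in res.boxes) >= 0.3


class TestMotionPipeline:
    def test_identical_frames_absent(self, cfg, rng):
        frame = rng.integers(0, 200, size=(60, 80), dtype=np.uint8)
        assert not run_motion_pipeline(frame, frame.copy(), cfg).present

    def test_translated_blob_detected_near_union(self, cfg):
        a, box_a = animal_frame(noise=0.0, pos=(30, 40))
        b, box_b = animal_frame(noise=0.0, pos=(30, 44))
        res = run_motion_pipeline(a, b, cfg)
        assert res.present
        union = (box_a[0], box_a[1], box_b[2], box_b[3])
        assert max(iou(bb, union) for bb in res.boxes) >= 0.3

    def test_static_warm_distractor_ignored(self, cfg, rng):
        base = np.full((60, 80), 40.0)
        base[20:35, 30:55] = 200.0  # static warm building
        a = np.clip(base + rng.normal(0, 3, base.shape), 0, 255).astype(np.uint8)
        b = np.clip(base + rng.normal(0, 3, base.shape), 0, 255).astype(np.uint8)
        assert not run_motion_pipeline(a, b, cfg).present

    def test_shape_mismatch_raises(self, cfg):
        with pytest.raises(ShapeError):
            run_motion_pipeline(
                np.zeros((4, 4), np.uint8), np.zeros((5, 4), np.uint8), cfg
            )

    def test_difference_invariant_to_static_overlay(self, rng):
        # Eq. |prev-curr|: adding the same overlay to both frames cancels
        for _ in range(10):
            a = rng.integers(0, 100, size=(20, 20), dtype=np.uint8)
            b = rng.integers(0, 100, size=(20, 20), dtype=np.uint8)
            overlay = rng.integers(0, 100, size=(20, 20), dtype=np.uint8)
            np.testing.assert_array_equal(
                abs_difference(a + overlay, b + overlay), abs_difference(a, b)
            )


class TestBoundaryEvents:
    def _res(self, fid, present=False, border=False):
        return DetectionResult(
            frame_id=fid, present=present, boxes=[], elapsed_s=0.0,
            method="motion", border_present=border,
        )

    def test_entry_rule(self):
        hist = [self._res("f0"), self._res("f1", border=True)]
        kinds = [e.kind for e in classify_boundary_events(hist)]
        assert kinds == [EventKind.ABSENT, EventKind.ENTERED]

    def test_exit_rule(self):
        hist = [self._res("f0", present=True), self._res("f1", border=True)]
        kinds = [e.kind for e in classify_boundary_events(hist)]
        assert kinds == [EventKind.PRESENT, EventKind.EXITING]

    def test_all_absent(self):
        hist = [self._res(f"f{i}") for i in range(4)]
        assert all(e.kind == EventKind.ABSENT for e in classify_boundary_events(hist))


class TestRunSequence:
    def _seq(self, frames):
        return FrameSequence(
            frames=frames,
            timestamps=[float(i) for i in range(len(frames))],
            frame_ids=[f"f{i}" for i in range(len(frames))],
        )

    def test_single_frame_bilateral(self, cfg):
        seq = self._seq([np.zeros((30, 30), dtype=np.uint8)])
        assert len(run_sequence(seq, "bilateral", cfg)) == 1

    def test_motion_pairing_marks_first_frame_unscored(self, cfg):
        seq = self._seq([np.zeros((20, 20), dtype=np.uint8)] * 10)
        results = run_sequence(seq, "motion", cfg)
        assert len(results) == 10
        assert not results[0].scored
        assert sum(r.scored for r in results) == 9

    def test_motion_needs_two_frames(self, cfg):
        seq = self._seq([np.zeros((20, 20), dtype=np.uint8)])
        with pytest.raises(EmptyInputError):
            run_sequence(seq, "motion", cfg)

    def test_unknown_method_rejected(self, cfg):
        seq = self._seq([np.zeros((20, 20), dtype=np.uint8)])
        with pytest.raises(ParameterError):
            run_sequence(seq, "yolo", cfg)

    def test_all_zero_sequence_never_detects(self, cfg):
        seq = self._seq([np.zeros((40, 40), dtype=np.uint8)] * 3)
        for method in ("bilateral", "canny", "motion"):
            assert not any(r.present for r in run_sequence(seq, method, cfg))

    def test_deterministic_rerun(self, cfg):
        frame, _ = animal_frame()
        seq = self._seq([frame, np.roll(frame, 3, axis=1)])
        for method in ("bilateral", "canny", "quantize", "motion"):
            r1 = run_sequence(seq, method, cfg)
            r2 = run_sequence(seq, method, cfg)
            assert [(r.frame_id, r.present, r.boxes) for r in r1] == [
                (r.frame_id, r.present, r.boxes) for r in r2
            ]
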