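from collections import Counter

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from wildtherm.contours import Contour, find_contours, reject_border_contours
from wildtherm.errors import ConfigurationError, ParameterError
from wildtherm.features import (
    FeatureSet,
    Keypoint,
    MatchDecisionParams,
    ReferenceChip,
    decide_animal,
    detect_features,
    match_features,
)
from wildtherm.filters import ThresholdParams, threshold

import oracles
from conftest import animal_template


def random_feature_set(rng, n) -> FeatureSet:
    desc = rng.normal(size=(n, 128))
    desc /= np.linalg.norm(desc, axis=1, keepdims=True)
    kps = tuple(Keypoint(row=float(i), col=0.0, sigma=1.6, orientation_deg=0.0)
                for i in range(n))
    return FeatureSet(keypoints=kps, descriptors=desc)


class TestDetectFeatures:
    def test_constant_region_has_no_keypoints(self):
        assert len(detect_features(np.full((20, 20), 128, dtype=np.uint8))) == 0

    def test_bright_blob_keypoint_near_center(self):
        img = np.zeros((33, 33))
        img[16, 16] = 255 * 20
        img = np.clip(gaussian_filter(img, 2.5), 0, 255).astype(np.uint8)
        fs = detect_features(img)
        assert len(fs) >= 1
        d = min(np.hypot(k.row - 16, k.col - 16) for k in fs.keypoints)
        assert d <= 2.0

    def test_small_region_warns_and_returns_empty(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.warns(UserWarning, match="64"):
            fs = detect_features(img)
        assert len(fs) == 0

    def test_translation_equivariance(self):
        tmpl = animal_template()
        a = np.full((48, 48), 50, dtype=np.uint8)
        b = np.full((48, 48), 50, dtype=np.uint8)
        a[10:36, 10:32] = tmpl
        b[13:39, 15:37] = tmpl  # shifted by (3, 5)
        fa, fb = detect_features(a), detect_features(b)
        assert len(fa) and len(fb)
        d = cdist(fb.descriptors, fa.descriptors)
        offsets = Counter()
        for i in range(d.shape[0]):
            j = int(np.argmin(d[i]))
            offsets[
                (round(fb.keypoints[i].row - fa.keypoints[j].row),
                 round(fb.keypoints[i].col - fa.keypoints[j].col))
            ] += 1
        assert offsets.most_common(1)[0][0] == (3, 5)

    def test_deterministic(self):
        tmpl = animal_template()
        f1, f2 = detect_features(tmpl), detect_features(tmpl)
        np.testing.assert_array_equal(f1.descriptors, f2.descriptors)
        assert f1.keypoints == f2.keypoints


class TestMatchFeatures:
    def test_identical_sets_all_match(self):
        fs = detect_features(animal_template())
        assert len(fs) > 0
        assert match_features(fs, fs) == len(fs)

    def test_empty_reference_gives_zero(self, rng):
        fs = random_feature_set(rng, 5)
        empty = FeatureSet(keypoints=(), descriptors=np.empty((0, 128)))
        assert match_features(fs, empty) == 0
        assert match_features(empty, fs) == 0

    def test_matches_exhaustive_oracle_exactly(self, rng):
        p = MatchDecisionParams(ratio=0.8)
        for _ in range(20):
            q = random_feature_set(rng, int(rng.integers(1, 12)))
            r = random_feature_set(rng, int(rng.integers(1, 12)))
            assert match_features(q, r, p) == oracles.match_count_bf(
                q.descriptors, r.descriptors, 0.8
            )

    def test_self_match_dominates_disjoint_reference(self, rng):
        for _ in range(10):
            a = random_feature_set(rng, 8)
            b = random_feature_set(rng, 8)
            assert match_features(a, a) >= match_features(a, b)


class TestDecideAnimal:
    @pytest.fixture()
    def chip(self):
        # crop of the template's thresholdable silhouette
        return ReferenceChip(image=animal_template()[3:24, 3:20], label="deer")

    def _noisy_scene(self, chip):
        """Animal pasted from the template plus a plain square distractor."""
        rng = np.random.default_rng(5)
        frame = np.full((64, 64), 60.0)
        frame[20:46, 12:34] = animal_template()
        frame[40:52, 44:56] = 200.0
        frame = np.clip(frame + rng.normal(0, 4, frame.shape), 0, 255).astype(np.uint8)
        binary = threshold(frame, ThresholdParams(180))
        return frame, reject_border_contours(find_contours(binary))

    def test_no_contours_means_absent(self, chip):
        present, hits = decide_animal(np.zeros((10, 10), np.uint8), [], [chip])
        assert (present, hits) == (False, [])

    def test_empty_library_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            decide_animal(np.zeros((10, 10), np.uint8), [], [])

    def test_region_equal_to_chip_self_matches(self, chip):
        h, w = chip.image.shape
        frame = np.zeros((40, 40), dtype=np.uint8)
        frame[5 : 5 + h, 7 : 7 + w] = chip.image
        ct = Contour(
            points=((5, 7),), bbox=(5, 7, 5 + h, 7 + w),
            touches_border=False, area_px=h * w,
        )
        present, hits = decide_animal(frame, [ct], [chip])
        assert present
        assert hits[0][1] == "deer"
        assert hits[0][2] >= len(chip.features)

    def test_animal_found_distractor_ignored_under_noise(self, chip):
        frame, contours = self._noisy_scene(chip)
        assert len(contours) == 2
        present, hits = decide_animal(frame, contours, [chip])
        assert present
        assert len(hits) == 1
        r0, c0, r1, c1 = hits[0][0].bbox
        # the hit overlaps the pasted animal, not the square at (40:52, 44:56)
        assert r0 < 46 and c1 < 40

    def test_monotone_in_min_good_matches(self, chip):
        frame, contours = self._noisy_scene(chip)
        prev_present = True
        for mg in range(1, 12):
            present, _ = decide_animal(
                frame, contours, [chip], MatchDecisionParams(min_good_matches=mg)
            )
            assert prev_present or not present  # raising mg never flips F->T
            prev_present = present

    def test_tiny_contours_skipped_without_fallback(self, chip):
        frame = np.zeros((30, 30), dtype=np.uint8)
        frame[10:12, 10:12] = 255
        ct = find_contours(frame)[0]
        present, _ = decide_animal(frame, [ct], [chip])
        assert not present  # area 4 < min_contour_area 9
        present, _ = decide_animal(
            frame, [ct], [chip],
            MatchDecisionParams(min_contour_area=1, fallback_area=4),
        )
        assert present  # area fallback accepts it

    def test_chip_smaller_than_8x8_rejected(self):
        with pytest.raises(ParameterError):
            ReferenceChip(image=np.zeros((4, 4), dtype=np.uint8), label="tiny")
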