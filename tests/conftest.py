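import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def animal_template() -> np.ndarray:
    """Synthetic warm-animal silhouette with distinctive interior structure.

    The outer ellipse sits at 200 (above the 180 detection threshold) and the
    interior carries patches of differing size and contrast so the feature
    detector finds distinctive keypoints.
    """
    t = np.full((26, 22), 60.0)
    rr, cc = np.ogrid[:26, :22]
    t[((rr - 13) / 10.0) ** 2 + ((cc - 11) / 8.0) ** 2 <= 1] = 200
    t[((rr - 8) / 3.0) ** 2 + ((cc - 8) / 2.0) ** 2 <= 1] = 250
    t[((rr - 17) / 1.5) ** 2 + ((cc - 14) / 1.5) ** 2 <= 1] = 232
    t[((rr - 11) / 2.0) ** 2 + ((cc - 15) / 3.0) ** 2 <= 1] = 120  # cool patch
    t[((rr - 18) / 2.5) ** 2 + ((cc - 7) / 1.5) ** 2 <= 1] = 215
    return t.astype(np.uint8)


def template_chip():
    from wildtherm.features import ReferenceChip

    return ReferenceChip(image=animal_template()[3:24, 3:20], label="deer")
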