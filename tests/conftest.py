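import numpy as np
import pytest
from hypothesis import settings as _hypothesis_settings

from alvedef.annotations import DefectClass, LandmarkPair, SliceAnnotation
from alvedef.phantom import PhantomSpec, generate_dataset

_hypothesis_settings.register_profile("deterministic", derandomize=True)
_hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Small phantom geometry used across tests."""
    return PhantomSpec(image_height_px=112, image_width_px=80)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(12, 2, small_spec, seed=7)


def random_annotation(rng, shape=(112, 80), pitch=0.25, classes=None):
    """A random valid slice annotation (helper shared by several tests)."""
    h, w = shape
    defects = []
    for c in classes if classes is not None else DefectClass:
        if classes is None and rng.uniform() < 0.5:
            continue
        while True:
            p1 = rng.uniform([2, 2], [w - 3, h - 3])
            p2 = p1 + rng.uniform(-20, 20, size=2)
            if 2 <= p2[0] <= w - 3 and 2 <= p2[1] <= h - 3 and np.hypot(*(p2 - p1)) > 4:
                break
        defects.append(LandmarkPair(c, p1, p2))
    return SliceAnnotation(
        patient_id="P0",
        tooth_id="P0_T0",
        slice_index=int(rng.integers(0, 3)),
        pixel_pitch_mm=pitch,
        defects=defects,
    )
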