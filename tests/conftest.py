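import numpy as np
import pytest

from lnfusion import cohort


@pytest.fixture(scope="session")
def validation_fixture():
    return cohort.make_validation_fixture()


@pytest.fixture(scope="session")
def model_fixture():
    return cohort.make_model_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_elastogram(rng, max_side=64):
    """Random RGB image + non-empty random ROI for oracle comparisons."""
    h = int(rng.integers(8, max_side + 1))
    w = int(rng.integers(8, max_side + 1))
    img = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    roi = rng.random((h, w)) < 0.5
    if not roi.any():
        roi[h // 2, w // 2] = True
    return img, roi
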