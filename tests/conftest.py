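import numpy as np
import pytest

from wildagree import (
    Annotation,
    BoundingBox,
    ImageMeta,
    morphology_scheme,
    waterfowl_scheme,
)


@pytest.fixture(scope="session")
def morph_scheme():
    return morphology_scheme()


@pytest.fixture(scope="session")
def species_scheme():
    return waterfowl_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_annotation(cx, cy, w=20.0, h=20.0, observer="obs01", image="img0", label="duck"):
    return Annotation(observer, image, BoundingBox(cx - w / 2, cy - h / 2, w, h), label)


@pytest.fixture
def ann_factory():
    return make_annotation


@pytest.fixture
def small_meta():
    return ImageMeta("img0", 684, 521)
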