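import numpy as np
import pytest

from vta_atlas.image_io import BinaryMask
from vta_atlas.synthetic import CohortSpec, make_cohort, make_phantom_subject


def iso_affine(size_mm: float, translation=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag([size_mm, size_mm, size_mm, 1.0])
    aff[:3, 3] = translation
    return aff


def mask_from_voxels(voxels, shape=(12, 12, 12), affine=None) -> BinaryMask:
    data = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        data[tuple(v)] = 1
    return BinaryMask(data=data, affine=affine if affine is not None else np.eye(4))


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    return CohortSpec(seed=1)


@pytest.fixture(scope="session")
def phantom_subject(default_spec):
    return make_phantom_subject(default_spec, 0)


@pytest.fixture(scope="session")
def cohort27(default_spec):
    """Full-size synthetic cohort shared across agreement/atlas tests."""
    return make_cohort(default_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
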