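import logging

import numpy as np
import pytest

from thalrad.features import FeatureConfig, RoiMask, VoxelGrid
from thalrad.io import extract_table
from thalrad.synthetic import CohortSpec, generate_cohort

# keep the fallback warnings of the selection stage out of test output
logging.getLogger("thalrad").setLevel(logging.ERROR)

# a small texture roster that still covers both matrix families; used by the
# cohort-level fixtures to keep extraction cheap
SMALL_CONFIG = FeatureConfig(
    n_levels=16,
    channels=(1,),
    glcm_features=("correlation", "energy", "entropy", "homogeneity2"),
    glrlm_features=("sre", "lre", "rln"),
)


def random_roi(rng: np.random.Generator, shape=(12, 12, 12), spacing=(1, 1, 1)):
    """A random blob-ish mask with a smooth random volume."""
    from scipy.ndimage import gaussian_filter

    vol = gaussian_filter(rng.standard_normal(shape), 1.2, mode="wrap")
    mask = np.zeros(shape, dtype=bool)
    c = np.array(shape) // 2
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    mask = (
        ((zz - c[0]) / (shape[0] * 0.3)) ** 2
        + ((yy - c[1]) / (shape[1] * 0.3)) ** 2
        + ((xx - c[2]) / (shape[2] * 0.3)) ** 2
    ) <= 1.0
    return VoxelGrid(vol, spacing), RoiMask(mask)


def cohort_table(spec: CohortSpec, config: FeatureConfig = SMALL_CONFIG):
    """Generate a cohort and return (feature table, 0/1 labels, dataset ids)."""
    images, records = generate_cohort(spec)
    table, failures = extract_table(
        images, [r.subject_id for r in records], config
    )
    assert not failures
    y = np.array([1 if r.class_label == "patient" else 0 for r in records])
    ds = np.array([r.dataset_id for r in records])
    return table, y, ds


@pytest.fixture(scope="session")
def strong_small_table():
    """A small, clearly separable cohort shared by several fast tests."""
    spec = CohortSpec(
        n_per_class=10, grid_shape=(14, 14, 14), texture_effect=3.0, seed=42
    )
    return cohort_table(spec)


@pytest.fixture(scope="session")
def strong_cohort_table():
    """A 60-subject strong-effect cohort for accuracy-level assertions."""
    spec = CohortSpec(
        n_per_class=30, grid_shape=(16, 16, 16), texture_effect=3.0, seed=33
    )
    return cohort_table(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
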