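"""Shared fixtures: synthetic cohorts at two scales.

The small 32-voxel cohorts keep module-level tests fast; the 64-voxel
cohort is the full benchmark scale used by the end-to-end tests.
"""

import numpy as np
import pytest

from gliopipe.phantom import PhantomSpec, generate_cohort
from gliopipe.volume_io import LesionLabelMap


@pytest.fixture(scope="session")
def cohort_small():
    """20 phantoms (10 per grade) on a 32^3 grid."""
    return generate_cohort(10, PhantomSpec(grid_shape=(32, 32, 32)), seed=3)


@pytest.fixture(scope="session")
def cohort_benchmark():
    """40 phantoms (20 per grade) on the default 64^3 grid."""
    return generate_cohort(20, PhantomSpec(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_label_map(rng, shape=(8, 8, 8), p_lesion=0.3) -> LesionLabelMap:
    """Random BraTS-labelled map: background-heavy with all three lesion labels."""
    labels = rng.choice(
        [0, 1, 2, 4], size=shape, p=[1 - p_lesion, p_lesion / 3, p_lesion / 3, p_lesion / 3]
    )
    return LesionLabelMap(labels.astype(np.int16))
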