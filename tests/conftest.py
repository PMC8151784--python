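import numpy as np
import pytest

from stablerec.cnn_features import SeededAlexNetBackend
from stablerec.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def backend():
    return SeededAlexNetBackend(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(
        n_patients=12, image_size=96, lesion_diameter_range=(20, 48), seed=3
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def random_roi():
    return np.random.default_rng(7).random((227, 227))
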