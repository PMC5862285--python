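import numpy as np
import pytest

from embryotk import phantom_gen
from embryotk.types import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture
def small_uint16(rng):
    return Volume3D(rng.integers(0, 65536, (6, 7, 8), dtype=np.uint16),
                    (2.0, 3.0, 4.0), {"centre": "HAR", "modality": "microCT"})


@pytest.fixture(scope="session")
def five_organ_phantom():
    """Clean 5-organ embryo phantom shared by segmentation/volumetry tests."""
    return phantom_gen.make_embryo_phantom(
        phantom_gen.five_organ_spec(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_five_organ_phantom():
    return phantom_gen.make_embryo_phantom(
        phantom_gen.five_organ_spec(noise_sd=15.0, seed=7))
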