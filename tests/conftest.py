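import numpy as np
import pytest

from neonirs.montage import make_montage
from neonirs.simulate import GroundTruth, NoiseSpec, make_test_schedule


@pytest.fixture(scope="session")
def montage8():
    return make_montage(8)


@pytest.fixture(scope="session")
def montage52():
    return make_montage(52)


@pytest.fixture()
def quiet_truth():
    """Unit-amplitude evoked responses, all noise sources off."""
    return GroundTruth.null(noise=NoiseSpec.quiet(), base_amplitude=1.0)


@pytest.fixture()
def schedule24():
    return make_test_schedule(12, 12, 6.0, (12.0, 16.0), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
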