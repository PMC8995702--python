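import numpy as np
import pytest

from laryngometry import PhantomConfig, generate_laryngeal_scene, generate_oropharyngeal_scene


@pytest.fixture(scope="session")
def laryngeal_scene():
    """Default laryngeal phantom, shared read-only across tests."""
    return generate_laryngeal_scene(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def oropharyngeal_scene():
    """Default oropharyngeal phantom with a 10 mm depth step."""
    return generate_oropharyngeal_scene(PhantomConfig(seed=7, depth_offset_mm=10.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
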