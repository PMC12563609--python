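import numpy as np
import pytest

from drwnet.synth import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config():
    return SceneConfig(size=128)


@pytest.fixture(scope="session")
def scene_g3(small_config):
    return generate_scene(3, 7, small_config)


@pytest.fixture(scope="session")
def scene_g0(small_config):
    return generate_scene(0, 7, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
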