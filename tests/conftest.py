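import numpy as np
import pytest

from plumascape.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def world_cfg():
    """Default synthetic world at the standard study conditions."""
    return WorldConfig(seed=7)


@pytest.fixture(scope="session")
def world(world_cfg):
    return generate_world(world_cfg)


@pytest.fixture(scope="session")
def small_cfg():
    """A coarse, fast world for pipeline-level tests."""
    return WorldConfig(seed=3, cell=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
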