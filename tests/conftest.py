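import numpy as np
import pytest

from birthlink.synth import GeneratorConfig, generate_world


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """A scaled-down study: 80 clusters, 50 facilities, ~600 births."""
    return GeneratorConfig(
        n_clusters=80,
        n_facilities=50,
        n_births=600,
        seed=11,
        region_bbox=(-14.6, -13.8, 34.0, 34.9),
        friction_resolution=2000.0,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    return generate_world(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
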