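import numpy as np
import pytest

from cstlesion import maps, phantom


@pytest.fixture(scope="session")
def space():
    """Compact template space with all portions and bands."""
    return phantom.build_phantom_space(
        shape=(24, 24, 110), tract_radius=2.0, fan_radius=3.5
    )


@pytest.fixture(scope="session")
def hc_cohort(space):
    return phantom.simulate_hc_cohort(space, n=21, seed=1234)


@pytest.fixture(scope="session")
def atlas(hc_cohort):
    return maps.build_normative_atlas(
        [maps.QuantMap(s.quant_maps["MTR"]) for s in hc_cohort]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(99)
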