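import numpy as np
import pytest

from combosyn.simulate import DesignSpec, WorldSpec, generate_world
from combosyn.surfaces import HillCurve


@pytest.fixture(scope="session")
def reduced_world():
    """Small synthetic world (8 drugs, 8 cell lines) shared across tests."""
    return generate_world(WorldSpec(seed=7), DesignSpec(5, 3, 8))


def random_curve(rng) -> HillCurve:
    """A realistic decreasing Hill curve drawn from broad parameter ranges."""
    return HillCurve(
        e0=rng.normal(100.0, 2.0),
        einf=rng.uniform(0.0, 50.0),
        ec50=10 ** rng.uniform(-1.5, 1.0),
        h=rng.uniform(0.5, 3.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
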