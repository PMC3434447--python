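import numpy as np
import pytest

from surfscape import EpParameters, FixtureSpec, make_fixture
from surfscape.core import ScalarGrid


@pytest.fixture
def dipole():
    structure, f = make_fixture(FixtureSpec(kind="dipole"))
    return structure


@pytest.fixture
def monopole():
    structure, f = make_fixture(FixtureSpec(kind="monopole"))
    return structure


@pytest.fixture
def ep_params():
    return EpParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_grid(rng, counts=(5, 4, 3)):
    return ScalarGrid(
        origin=rng.uniform(-5, 5, 3),
        spacing=rng.uniform(0.5, 2.0, 3),
        values=rng.standard_normal(counts),
    )
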