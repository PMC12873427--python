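import numpy as np
import pytest

from clcmech import synthetic as syn


@pytest.fixture(scope="session")
def wire_fixture():
    """Small always-wired trajectory shared by read-only tests."""
    return syn.make_wire_fixture(n_frames=20, wire_probability=1.0, seed=11)


@pytest.fixture(scope="session")
def density_fixture():
    return syn.make_density_fixture(seed=21)


@pytest.fixture(scope="session")
def hdx_fixture():
    return syn.make_hdx_curves(peptides=(("p1", 10, 25),),
                               protection_factors=(1000.0,),
                               noise=0.0, seed=31)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
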