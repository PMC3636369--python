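import numpy as np
import pytest

from ldfkit import fixtures as fx


@pytest.fixture(scope="session")
def library():
    return fx.reference_nuclides()


@pytest.fixture(scope="session")
def chain_library():
    return fx.synthetic_chain()


@pytest.fixture(scope="session")
def decay_graph():
    return fx.pure_decay_landscape()


@pytest.fixture(scope="session")
def graph3():
    return fx.generate_landscape(fx.FixtureSpec(n_objects=3))


@pytest.fixture(scope="session")
def graph1():
    return fx.generate_landscape(fx.FixtureSpec(n_objects=1))


@pytest.fixture(scope="session")
def wetland_object(graph1):
    """The fixture object's parameters, valid at any post-succession time."""
    return graph1.objects["obj1"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
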