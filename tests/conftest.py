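import numpy as np
import pytest

from glycodock.fixtures import (
    FixtureSpec,
    make_chain,
    make_complex,
    standard_fixture_spec,
)
from glycodock.structure_io import assign_atom_types, define_site


@pytest.fixture(scope="session")
def disaccharide():
    return make_chain(FixtureSpec(chain_length=2))


@pytest.fixture(scope="session")
def tetrasaccharide():
    return make_chain(FixtureSpec(chain_length=4))


@pytest.fixture(scope="session")
def hexasaccharide():
    return make_chain(FixtureSpec(chain_length=6))


@pytest.fixture(scope="session")
def standard_complex():
    """Tight tetrasaccharide groove with its planted, score-relaxed native pose."""
    receptor, chain, native = make_complex(standard_fixture_spec())
    site = define_site(receptor, native)
    return receptor, chain, native, site


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
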