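import numpy as np
import pytest

import dtlpareto as dl


@pytest.fixture(scope="session")
def fig_species():
    """The four-taxon dated species tree used throughout the examples:
    ((A,B)x,(C,D)y)r with times x=1, y=2, r=3."""
    return dl.parse_species_tree("((A,B)x,(C,D)y)r;", {"x": 1, "y": 2, "r": 3})


@pytest.fixture(scope="session")
def fig_sp(fig_species):
    return dl.subdivide(fig_species)


@pytest.fixture(scope="session")
def cherry_species():
    return dl.parse_species_tree("(A,B)x;", {"x": 1})


@pytest.fixture(scope="session")
def cherry_sp(cherry_species):
    return dl.subdivide(cherry_species)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
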