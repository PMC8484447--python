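import numpy as np
import pytest

from holoeve.eve import OUGeneParams, SampleLayout
from holoeve.phylogeny import Phylogeny, three_taxon_tree


@pytest.fixture(scope="session")
def tree():
    return three_taxon_tree()


@pytest.fixture(scope="session")
def two_tip_tree():
    return Phylogeny.from_newick("(X:1,Y:1);")


@pytest.fixture
def layout3x3():
    """Three species, three individuals each (control-arm layout)."""
    return SampleLayout(species=("A",) * 3 + ("B",) * 3 + ("C",) * 3)


@pytest.fixture
def unit_params():
    return OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
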