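import numpy as np
import pytest

from nanobrush import builders
from nanobrush.core import MolecularSystem


@pytest.fixture(scope="session")
def cnt10():
    """The (10,0), 4.1 nm zigzag tube."""
    return builders.build_cnt(builders.CNTSpec(n=10, m=0, length=4.1))


@pytest.fixture(scope="session")
def gly24():
    return builders.build_homopeptide(builders.PeptideSpec("GLY", 24))


@pytest.fixture(scope="session")
def grafted8(cnt10):
    """Tube with 8 PEO 18-mers."""
    return builders.graft_chains(cnt10, builders.GraftSpec(n_chains=8))


@pytest.fixture(scope="session")
def adsorption_system(cnt10, gly24):
    """Tube + free-floating polyglycine in a 12 nm box (no solvent)."""
    return MolecularSystem.concat(
        [cnt10, gly24.translated([2.5, 0.0, 0.0])], box=12.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
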