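import numpy as np
import pytest

from dimerlab.synth import InterfaceSpec, make_toy_dimer


@pytest.fixture(scope="session")
def toy_dimer():
    """A 42-residue-per-monomer toy dimer with a (5,2,3) planted interface."""
    return make_toy_dimer(42, InterfaceSpec(n_hydrophobic_pairs=5, n_ionic_pairs=2,
                                            n_hbond_pairs=3, seed=1))


@pytest.fixture(scope="session")
def small_dimer():
    """A 12-residue toy dimer (3 interface slots), cheap enough for MC tests."""
    return make_toy_dimer(12, InterfaceSpec(n_hydrophobic_pairs=2, n_ionic_pairs=1,
                                            n_hbond_pairs=0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
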