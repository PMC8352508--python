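import pytest

from decoykit.chem import Molecule
from decoykit.fixtures import FixtureSpec, make_library
from decoykit.generator import DecoyGenerator
from decoykit.pairs import PairConfig, build_pairs


@pytest.fixture(scope="session")
def fixture_library():
    """120 small valid molecules with many shared compositions."""
    return make_library(FixtureSpec(
        n_molecules=120, atom_range=(5, 7),
        palette=("C", "C", "C", "C", "N", "O"), seed=3))


@pytest.fixture(scope="session")
def loose_pairs(fixture_library):
    """Training pairs under relaxed thresholds (desk-scale training data)."""
    cfg = PairConfig(max_structural_sim=0.7, max_property_distance=4.0,
                     property_set="dude6")
    return build_pairs(fixture_library, cfg)


@pytest.fixture(scope="session")
def trained_model(loose_pairs):
    """A small generator trained once per session on fixture pairs."""
    model = DecoyGenerator(epochs=12, random_state=0)
    model.fit(loose_pairs[:30])
    return model


@pytest.fixture
def ethanol():
    return Molecule.from_smiles("CCO")


@pytest.fixture
def benzene():
    return Molecule.from_smiles("c1ccccc1")
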