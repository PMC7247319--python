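import numpy as np
import pytest

from memtide.gcs import ElectrolyteComposition, Ion
from memtide.membranes import MembraneSpec, load_species_library


@pytest.fixture(scope="session")
def lipid_library():
    return load_species_library()


@pytest.fixture(scope="session")
def tocl_membrane(lipid_library):
    return MembraneSpec.from_fractions(
        {"TOCL": 0.2, "POPC": 0.8}, lipid_library
    )


@pytest.fixture(scope="session")
def popg_membrane(lipid_library):
    return MembraneSpec.from_fractions(
        {"POPG": 0.2, "POPC": 0.8}, lipid_library
    )


@pytest.fixture(scope="session")
def mlcl_membrane(lipid_library):
    return MembraneSpec.from_fractions(
        {"MLCL": 0.2, "POPC": 0.8}, lipid_library
    )


@pytest.fixture(scope="session")
def popc_membrane(lipid_library):
    return MembraneSpec.from_fractions({"POPC": 1.0}, lipid_library)


@pytest.fixture
def kcl_20mM():
    return ElectrolyteComposition.symmetric(0.020)


@pytest.fixture
def kcl_100mM():
    return ElectrolyteComposition.symmetric(0.100)


@pytest.fixture
def calcium_electrolyte():
    """20 mM KCl + 50 uM CaCl2 with Stern-adsorbing cations."""
    return ElectrolyteComposition((
        Ion("K", 1, 0.020, stern_k=0.6),
        Ion("Ca", 2, 50e-6, stern_k=12.0),
        Ion("Cl", -1, 0.020 + 2 * 50e-6),
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
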