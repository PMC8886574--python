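import numpy as np
import pytest

from equichel import ChemicalSystem, Species, load_model


@pytest.fixture(scope="session")
def fe_6a():
    return load_model("fe_6a_water")


@pytest.fixture(scope="session")
def fe_11a():
    return load_model("fe_11a_water")


@pytest.fixture(scope="session")
def fe_6d():
    return load_model("fe_6d_meoh")


@pytest.fixture(scope="session")
def all_complexing_models():
    return {name: load_model(name)
            for name in ("fe_6a_water", "fe_11a_water", "fe_10a_meoh",
                         "fe_6c_meoh", "fe_6d_meoh")}


@pytest.fixture
def monoprotic_ligand():
    """Ligand-only system with a single protonation, pKa 4.58."""
    return ChemicalSystem(species=(Species("LH", 0, 1, 1, 4.58),),
                          label="monoprotic ligand")


@pytest.fixture
def ml_only():
    """Toy 1:1 complex with no protonation and no hydrolysis."""
    return ChemicalSystem(species=(Species("ML", 1, 1, 0, 20.0),),
                          label="pure ML")


@pytest.fixture
def ml3_only():
    """Toy pure-ML3 system (single cooperative 1:3 complex)."""
    return ChemicalSystem(species=(Species("ML3", 1, 3, 0, 30.0),),
                          label="pure ML3")
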