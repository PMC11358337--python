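import pytest

from sabsim.chemistry import ChemistryParams
from sabsim.environment import get_preset, make_diel_forcing
from sabsim.metabolism import KineticParams
from sabsim.microclimate import MicroclimateParams
from sabsim.model import ModelParams


@pytest.fixture(scope="session")
def kinetics():
    return KineticParams()


@pytest.fixture(scope="session")
def chem_params():
    return ChemistryParams()


@pytest.fixture(scope="session")
def micro_params():
    return MicroclimateParams()


@pytest.fixture(scope="session")
def model_params():
    return ModelParams()


@pytest.fixture(scope="session")
def summer_forcing():
    return make_diel_forcing(get_preset("summer"))


@pytest.fixture(scope="session")
def winter_forcing():
    return make_diel_forcing(get_preset("winter"))
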