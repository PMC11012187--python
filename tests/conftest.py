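import pytest

import mae_lipidomics as ml


@pytest.fixture(scope="session")
def design():
    return ml.default_design()


@pytest.fixture(scope="session")
def zero_noise_responses(design):
    return ml.gen_ffd_responses(design, ml.GeneratorConfig(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def fixture_table():
    return ml.gen_lipid_fixture()


@pytest.fixture(scope="session")
def fixture_species(fixture_table):
    return ml.read_identification_table(fixture_table)


@pytest.fixture(scope="session")
def screening():
    return ml.gen_solvent_screening(ml.GeneratorConfig(seed=0))
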