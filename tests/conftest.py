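import pytest
from hypothesis import settings

from ligrest.fixtures import FIXTURE_NAMES, make_fixture, make_reference_table

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

TRP_CHI2 = ("CA", "CB", "CG", "CD1")
TRP_CHI2_CONFORMERS = (0.0, 90.0, -90.0)


@pytest.fixture(params=FIXTURE_NAMES)
def any_component(request):
    return make_fixture(request.param)


@pytest.fixture
def acetate():
    return make_fixture("acetate")


@pytest.fixture
def ethane():
    return make_fixture("ethane")


@pytest.fixture
def benzene():
    return make_fixture("benzene")


@pytest.fixture
def trp_sidechain():
    return make_fixture("trp_sidechain")


@pytest.fixture
def dipeptide_like():
    return make_fixture("dipeptide_like")


@pytest.fixture
def dicarboxylate():
    return make_fixture("dicarboxylate")


@pytest.fixture
def acetate_table(acetate):
    return make_reference_table([acetate])
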