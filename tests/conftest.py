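import pytest

import sbmlkit as sk
from sbmlkit import fixtures


def parse(fixture):
    model, _ = sk.read_sbml(fixture.sbml_text)
    return model


def network_for(fixture):
    return sk.compile_network(sk.preset_promotelocals_expandfuns(parse(fixture)))


@pytest.fixture(scope="session")
def decay_net():
    return network_for(fixtures.make_decay())


@pytest.fixture(scope="session")
def binding_nets():
    split = network_for(fixtures.make_reversible_binding())
    unsplit = network_for(fixtures.make_reversible_binding(splittable=False))
    return split, unsplit


@pytest.fixture(scope="session")
def event_net():
    return network_for(fixtures.make_event_model())


@pytest.fixture(scope="session")
def boundary_net():
    return network_for(fixtures.make_boundary_model())


@pytest.fixture(scope="session")
def immigration_net():
    return network_for(fixtures.make_immigration_death())
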