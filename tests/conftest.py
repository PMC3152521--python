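import pytest

import insomnia_cea as ic


@pytest.fixture(scope="session")
def unit_costs():
    return ic.load_unit_costs()


@pytest.fixture(scope="session")
def matrix():
    return ic.load_utilisation()


@pytest.fixture(scope="session")
def event_costs(matrix, unit_costs):
    return ic.build_event_costs(matrix, unit_costs)


@pytest.fixture(scope="session")
def insomnia_tree():
    return ic.build_insomnia_tree()


@pytest.fixture(scope="session")
def params():
    return ic.load_parameters()
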