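import pytest

import phenolog_kit as pk
from phenolog_kit.orthology import OrthologPair


@pytest.fixture
def triangle_pairs():
    """Three pairs collapsing into a single ortholog group {w1, w2, h1, h2}."""
    return [
        OrthologPair("w1", "h1", 100.0),
        OrthologPair("w1", "h2", 100.0),
        OrthologPair("w2", "h2", 100.0),
    ]


@pytest.fixture
def triangle_map(triangle_pairs):
    return pk.build_groups(triangle_pairs)


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario, seed 1."""
    return pk.SyntheticScenario(seed=1)


@pytest.fixture(scope="session")
def scenario_data(scenario):
    return pk.generate_all(scenario)


@pytest.fixture(scope="session")
def scan(scenario_data):
    return pk.lod_scan(
        scenario_data["traits"], scenario_data["genotypes"], scenario_data["markers"]
    )
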