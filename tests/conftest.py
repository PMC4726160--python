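import pytest

from magecs import make_fixture
from magecs.fixtures import fixture_config


@pytest.fixture(scope="session")
def fixture_genome():
    genome, truth = make_fixture(seed=1)
    return genome, truth


@pytest.fixture(scope="session")
def toy_config():
    return fixture_config(seed=1)
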