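import pytest
from hypothesis import settings

import strokeburden as sb

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def epi_table():
    return sb.default_epi_table()


@pytest.fixture(scope="session")
def cost_table():
    return sb.default_cost_table()


@pytest.fixture(scope="session")
def life_table():
    return sb.default_life_table()


@pytest.fixture(scope="session")
def wage_table():
    return sb.default_wage_table()


@pytest.fixture(scope="session")
def config():
    return sb.default_config()
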