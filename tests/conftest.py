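import pytest

from cyp2c19_cea.params import default_parameters
from cyp2c19_cea.pipeline import evaluate
from cyp2c19_cea.synth import default_schedule


@pytest.fixture()
def defaults():
    return default_parameters()


@pytest.fixture(scope="session")
def schedule():
    return default_schedule(default_parameters())


@pytest.fixture(scope="session")
def base_result(schedule):
    """Base-case pipeline result, shared across tests (deterministic)."""
    return evaluate(default_parameters(), schedule)
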