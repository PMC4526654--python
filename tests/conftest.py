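import pytest

from sinboole.logic_core import parse_rules
from sinboole.sin_model import build_final_model, build_nuc2_variant, expected_phenotypes


@pytest.fixture(scope="session")
def sin():
    return build_final_model()


@pytest.fixture(scope="session")
def nuc2_variant():
    return build_nuc2_variant()


@pytest.fixture(scope="session")
def training_expectations():
    return expected_phenotypes()


@pytest.fixture
def toggle_net():
    """One node negating itself: the smallest oscillator."""
    return parse_rules("A := NOT A")


@pytest.fixture
def toy2():
    """Mutual repression of two nodes: bistable under asynchronous update."""
    return parse_rules("A := NOT B\nB := NOT A")
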