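import pytest

from gesturelaws import (
    default_study_config,
    filter_complete,
    segment_sequences,
    simulate_tokens,
    table1_fixture_tokens,
)


@pytest.fixture(scope="session")
def study_tokens():
    """One study-scale simulated token stream shared across tests."""
    return simulate_tokens(default_study_config(seed=42))


@pytest.fixture(scope="session")
def study_sequences(study_tokens):
    kept, _ = filter_complete(segment_sequences(study_tokens))
    return kept


@pytest.fixture(scope="session")
def table1_tokens():
    """Deterministic stream realizing the published contingency table."""
    return table1_fixture_tokens()
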