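import pytest

from miscore import ScoreConfig, bundled_ontology


@pytest.fixture(scope="session")
def ontology():
    return bundled_ontology()


@pytest.fixture(scope="session")
def config():
    return ScoreConfig()
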