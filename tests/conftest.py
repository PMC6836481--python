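from __future__ import annotations

import pytest
from hypothesis import settings

from adiposcreen import GeneSet, GeneratorConfig, generate
from adiposcreen.fixtures import load_published_fixtures

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle shared across the session."""
    return generate(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def published_fixtures():
    return load_published_fixtures()


@pytest.fixture
def toy_gene_sets():
    def _gs(*symbols, label=""):
        return GeneSet.from_symbols(symbols, label=label)
    return _gs
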