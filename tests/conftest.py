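import pytest

from omopmap.fixtures import bundled_vocabulary
from omopmap.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def store():
    return bundled_vocabulary()


@pytest.fixture(scope="session")
def small_study(store):
    """A 120-patient prospective study with its ground-truth ledger."""
    config = GeneratorConfig(n_patients=120, seed=7)
    study, ledger = generate(config, store)
    return config, study, ledger
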