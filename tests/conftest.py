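import pytest

from twinrisk.config import default_config
from twinrisk.concordance import EpidemiologicalObservables


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def ms_observables(config):
    return config.observables


@pytest.fixture(scope="session")
def chain(config):
    from twinrisk.reports import adjusted_chain

    return adjusted_chain(config)


@pytest.fixture
def simple_observables():
    return EpidemiologicalObservables(
        prevalence=0.0015, mz_raw=0.25, dz_raw=0.054, sib_raw=0.029
    )
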