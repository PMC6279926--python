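import pytest

from digilamp.registry import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def maize(registry):
    return registry["genome"]


@pytest.fixture(scope="session")
def seed_tissue(registry):
    return registry["seed_tissue"]


@pytest.fixture(scope="session")
def bt11(registry):
    return registry["events"]["Bt11"]


@pytest.fixture(scope="session")
def mon810(registry):
    return registry["events"]["Mon810"]
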