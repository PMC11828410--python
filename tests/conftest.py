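import pytest

from conjkin import KineticParams, REFERENCE_PLASMIDS


@pytest.fixture(scope="session")
def pkm101() -> KineticParams:
    return REFERENCE_PLASMIDS["pKM101"]


@pytest.fixture(scope="session")
def rp4() -> KineticParams:
    return REFERENCE_PLASMIDS["RP4"]


@pytest.fixture(scope="session")
def r388() -> KineticParams:
    return REFERENCE_PLASMIDS["R388"]
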