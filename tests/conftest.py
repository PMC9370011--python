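import pytest
from hypothesis import settings

import scmfold as sf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fp_scale():
    return sf.load_scale("fauchere-pliska")


@pytest.fixture(scope="session")
def p53():
    return sf.make_p53_fixture()


@pytest.fixture(scope="session")
def default_config():
    return sf.ScanConfig()


@pytest.fixture(scope="session")
def p53_contacts(p53, fp_scale, default_config):
    return sf.scan_protein(p53, fp_scale, default_config)
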