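import pytest

from m6afold.params import load_m6a_params, load_rna_params


@pytest.fixture(scope="session")
def rna():
    return load_rna_params()


@pytest.fixture(scope="session")
def m6a():
    return load_m6a_params()


@pytest.fixture(scope="session")
def rna_legacy():
    return load_rna_params(legacy_gu_end=True)
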