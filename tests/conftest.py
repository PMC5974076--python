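import pytest

from editcall import build_reference, make_allele


@pytest.fixture(scope="session")
def ref():
    return build_reference(length=1626, seed=7)


@pytest.fixture(scope="session")
def scid(ref):
    return make_allele(ref, "SCID").sequence


@pytest.fixture(scope="session")
def corrected(ref):
    return make_allele(ref, "CORRECTED").sequence
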