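import pytest

from condorabc import make_condor_like_fixture


@pytest.fixture(scope="session")
def condor_fixture():
    """Default condor-like dataset: 73 samples, 6 haplotypes, 3 regions."""
    return make_condor_like_fixture(seed=0)
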