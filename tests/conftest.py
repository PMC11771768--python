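import pytest

from crypt4gh_stream import generate_keypair, seeded_rng


@pytest.fixture
def rng():
    """Deterministic byte source standing in for os.urandom."""
    return seeded_rng(0x5EED)


@pytest.fixture
def writer(rng):
    return generate_keypair(rng)


@pytest.fixture
def reader(rng):
    return generate_keypair(rng)


@pytest.fixture
def outsider(rng):
    """A key pair no container in the test is addressed to."""
    return generate_keypair(rng)
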