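import pytest

from groovescan import make_toy_complex, scan


@pytest.fixture(scope="session")
def toy3():
    """Default toy complex with a 3-bp duplex (64-motif scan space)."""
    return make_toy_complex(L=3)


@pytest.fixture(scope="session")
def toy4():
    return make_toy_complex(L=4)


@pytest.fixture(scope="session")
def toy8():
    return make_toy_complex(L=8)


@pytest.fixture(scope="session")
def scan_table3(toy3):
    """Full 64-motif scan of the 3-bp toy complex."""
    return scan(toy3)
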