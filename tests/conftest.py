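import warnings

import pytest

from sssl_epistasis.design import DEFAULT_LOCI, enumerate_materials


@pytest.fixture(scope="session")
def loci():
    return list(DEFAULT_LOCI)


@pytest.fixture(scope="session")
def materials65(loci):
    return enumerate_materials(loci, max_order=3)


@pytest.fixture(scope="session")
def materials33(loci):
    return enumerate_materials(loci, max_order=2)


@pytest.fixture(autouse=True)
def _silence_truncation_warnings():
    # noise-free simulations legitimately truncate tiny negative components
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="negative variance estimates truncated"
        )
        yield
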