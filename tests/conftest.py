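import pytest

from stembark import SPECIES, load_packaged_library


@pytest.fixture(scope="session")
def libraries():
    """Packaged model libraries for all four species."""
    return {sp: load_packaged_library(sp) for sp in SPECIES}


@pytest.fixture(scope="session")
def aspen(libraries):
    return libraries["common_aspen"]
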