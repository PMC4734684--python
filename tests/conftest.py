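import numpy as np
import pytest
from hypothesis import settings

from phosphobind import (
    SublibrarySpec,
    default_normalized_properties,
    enumerate_sublibrary,
    load_category_table,
    load_property_table,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def categories():
    return load_category_table()


@pytest.fixture(scope="session")
def raw_properties():
    return load_property_table()


@pytest.fixture(scope="session")
def norm():
    return default_normalized_properties()


@pytest.fixture(scope="session")
def paper_library_n():
    return enumerate_sublibrary(SublibrarySpec.paper("N"))


@pytest.fixture(scope="session")
def paper_library_c():
    return enumerate_sublibrary(SublibrarySpec.paper("C"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
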