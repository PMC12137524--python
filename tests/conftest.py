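import pytest
from hypothesis import settings

from packconform.formulary import builtin_catalogues, products_by_substance

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalogues():
    return builtin_catalogues()


@pytest.fixture(scope="session")
def recommendations(catalogues):
    return catalogues[0]


@pytest.fixture(scope="session")
def products(catalogues):
    return catalogues[1]


@pytest.fixture(scope="session")
def products_by_id(products):
    return {p.product_id: p for p in products}


@pytest.fixture(scope="session")
def packs_by_substance(products):
    return products_by_substance(products)
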