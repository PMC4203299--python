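import random

import pytest

import eolkit as ek
from eolkit import fixtures as fx


@pytest.fixture(scope="session")
def registry():
    return fx.build_worked_example_registry()


@pytest.fixture(scope="session")
def transport(registry):
    return fx.make_offline_transport(registry)


@pytest.fixture(scope="session")
def ursus_pages(transport):
    return ek.download_eol_pages([fx.URSUS_PAGE_ID], transport)


@pytest.fixture(scope="session")
def bear_pages(transport):
    return ek.download_searched_taxa(list(fx.BEAR_LINEAGES), transport, exact=True)


@pytest.fixture(scope="session")
def bear_hierarchy(bear_pages, transport):
    return ek.download_hierarchy(bear_pages, fx.NCBI, transport)


@pytest.fixture(scope="session")
def invasive_pages(transport):
    return ek.download_searched_taxa(list(fx.INVASIVE_SPECIES), transport, exact=True)


@pytest.fixture(scope="session")
def invasive_hierarchy(invasive_pages, transport):
    return ek.download_hierarchy(invasive_pages, fx.NCBI, transport)


def hierarchy_set_from_specs(specs) -> ek.HierarchySet:
    """Render specs to XML and parse them back, exercising the full
    generator→parser path on the way to a HierarchySet."""
    hset = ek.HierarchySet(provider=specs[0].provider)
    for spec in specs:
        hset.add(ek.parse_hierarchy_page(fx.generate_hierarchy_xml(spec)))
    return hset


def page_set_from_specs(specs) -> ek.PageSet:
    pages = ek.PageSet()
    for spec in specs:
        pages.add(ek.parse_eol_page(fx.generate_page_xml(spec)),
                  provenance=f"fixture:{spec.page_id}")
    return pages


def random_page_set(seed: int, n: int) -> ek.PageSet:
    rng = random.Random(seed)
    specs = [fx.random_page_spec(rng, page_id=1000 + i) for i in range(n)]
    return page_set_from_specs(specs)
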