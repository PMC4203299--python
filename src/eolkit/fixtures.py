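"""Synthetic-data backbone: declarative specs → EOL-dialect XML → an offline
transport, so every parser, extractor and tree builder is exercisable with no
network at all.

Three layers:

* ``PageSpec`` / ``HierSpec`` declare a taxon page or provider classification
  page; :func:`generate_page_xml` / :func:`generate_hierarchy_xml` render them
  to the exact dialect :mod:`eolkit.page_model` parses (the generators and
  parsers are mutual inverses, which the test suite leans on heavily).
* :class:`FixtureRegistry` maps rendered API URLs to XML bodies and answers
  search queries from a name index (exact normalized matches first, then
  case-insensitive substring hits, ties by ascending page id).
* :func:`build_worked_example_registry` packages the worked examples used
  throughout the documentation: the *Ursus* pages, the six "bears" (polar
  bear, koala, water bear, bear grass, bear's breeches, woolly bear) with
  NCBI-style lineages, and five invasive species with French vernacular
  names and NCBI synonyms.

Everything is deterministic for a given spec collection and seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from lxml import etree

from .api_client import (
    Transport,
    build_api_url,
    hierarchy_request,
    normalize_name,
    page_request,
)
from .errors import ContractError, DocumentNotFoundError
from .page_model import (
    CommonName,
    DataObject,
    EOLPage,
    HierarchyPage,
    RankedName,
    Synonym,
    TaxonConceptEntry,
)

LINNAEAN_RANKS = ("kingdom", "phylum", "class", "order", "family",
                  "genus", "species", "subspecies")


@dataclass
class PageSpec:
    """Declarative description of a taxon page; mirrors :class:`EOLPage`."""

    page_id: int
    scientific_name: str
    richness_score: float | None = None
    concepts: list[TaxonConceptEntry] = field(default_factory=list)
    data_objects: list[DataObject] = field(default_factory=list)
    common_names: list[CommonName] = field(default_factory=list)
    references: list[str] = field(default_factory=list)
    synonyms: list[Synonym] = field(default_factory=list)
    iucn_status: str | None = None

    def expected_page(self) -> EOLPage:
        """The record :func:`~eolkit.page_model.parse_eol_page` must return."""
        return EOLPage(
            page_id=self.page_id,
            scientific_name=self.scientific_name,
            richness_score=self.richness_score,
            concepts=list(self.concepts),
            data_objects=list(self.data_objects),
            common_names=list(self.common_names),
            references=list(self.references),
            synonyms=list(self.synonyms),
            iucn_status=self.iucn_status,
        )


@dataclass
class HierSpec:
    """Declarative description of a provider classification page."""

    entry_id: int
    provider: str
    taxon: RankedName
    ancestors: list[RankedName] = field(default_factory=list)
    children: list[RankedName] = field(default_factory=list)
    synonyms: list[Synonym] = field(default_factory=list)

    def expected_page(self) -> HierarchyPage:
        taxon = RankedName(self.taxon.name, self.taxon.rank, self.entry_id)
        return HierarchyPage(
            entry_id=self.entry_id,
            provider=self.provider,
            taxon=taxon,
            ancestors=list(self.ancestors),
            children=list(self.children),
            synonyms=list(self.synonyms),
        )


def _sub(parent, tag: str, text=None, **attrs):
    elem = etree.SubElement(parent, tag)
    if text is not None:
        elem.text = str(text)
    for k, v in attrs.items():
        elem.set(k, v)
    return elem


def _serialize(root) -> str:
    return etree.tostring(root, encoding="unicode", pretty_print=True)


def generate_page_xml(spec: PageSpec) -> str:
    """Render a PageSpec to taxon-page XML (validated through the record
    invariants first, so an invalid spec fails here, not at parse time)."""
    spec.expected_page()  # invariant check
    root = etree.Element("response")
    concept = _sub(root, "taxonConcept")
    _sub(concept, "taxonConceptID", spec.page_id)
    _sub(concept, "scientificName", spec.scientific_name)
    if spec.richness_score is not None:
        _sub(concept, "richnessScore", repr(float(spec.richness_score)))
    if spec.iucn_status is not None:
        _sub(concept, "iucnStatus", spec.iucn_status)
    for c in spec.concepts:
        entry = _sub(concept, "taxonConceptEntry")
        _sub(entry, "identifier", c.entry_id)
        _sub(entry, "provider", c.provider)
        _sub(entry, "canonicalName", c.canonical_name)
    for o in spec.data_objects:
        obj = _sub(concept, "dataObject")
        _sub(obj, "dataObjectID", o.object_id)
        _sub(obj, "dataType", o.data_type_uri)
        if o.mime_type is not None:
            _sub(obj, "mimeType", o.mime_type)
        if o.language is not None:
            _sub(obj, "language", o.language)
        for k, v in o.attributes.items():
            _sub(obj, k, v)
    for cn in spec.common_names:
        _sub(concept, "commonName", cn.name, language=cn.language,
             preferred="true" if cn.preferred else "false")
    for ref in spec.references:
        _sub(concept, "reference", ref)
    for s in spec.synonyms:
        _sub(concept, "synonym", s.name, relationship=s.relationship)
    return _serialize(root)


def generate_hierarchy_xml(spec: HierSpec) -> str:
    spec.expected_page()  # invariant check
    root = etree.Element("response")
    entry = _sub(root, "hierarchyEntry")
    _sub(entry, "entryID", spec.entry_id)
    _sub(entry, "provider", spec.provider)
    _sub(entry, "scientificName", spec.taxon.name)
    if spec.taxon.rank is not None:
        _sub(entry, "taxonRank", spec.taxon.rank)
    for group, tag in ((spec.ancestors, "ancestor"), (spec.children, "child")):
        for rn in group:
            elem = _sub(entry, tag)
            _sub(elem, "scientificName", rn.name)
            if rn.rank is not None:
                _sub(elem, "taxonRank", rn.rank)
            if rn.entry_id is not None:
                _sub(elem, "entryID", rn.entry_id)
    for s in spec.synonyms:
        _sub(entry, "synonym", s.name, relationship=s.relationship)
    return _serialize(root)


def generate_search_xml(hits: list[tuple[int, str]]) -> str:
    root = etree.Element("response")
    for page_id, title in hits:
        entry = _sub(root, "entry")
        _sub(entry, "id", page_id)
        _sub(entry, "title", title)
    return _serialize(root)


class FixtureRegistry:
    """Offline store mapping rendered API URLs to XML bodies.

    Page and classification documents are pre-rendered at registration;
    search responses are composed on demand from the name index, which keeps
    the mapping total over all queries while staying deterministic.
    """

    def __init__(self):
        self._pages: dict[int, str] = {}
        self._hierarchies: dict[int, str] = {}
        self._names: dict[int, str] = {}  # page_id -> scientific name

    def add_page(self, spec: PageSpec) -> None:
        self._pages[spec.page_id] = generate_page_xml(spec)
        self._names[spec.page_id] = spec.scientific_name

    def add_hierarchy(self, spec: HierSpec) -> None:
        self._hierarchies[spec.entry_id] = generate_hierarchy_xml(spec)

    def page_ids(self) -> list[int]:
        return list(self._pages)

    def entry_ids(self) -> list[int]:
        return list(self._hierarchies)

    def urls(self) -> list[str]:
        """Every id-addressed URL the registry serves."""
        return (
            [build_api_url(page_request(i)) for i in self._pages]
            + [build_api_url(hierarchy_request(i)) for i in self._hierarchies]
        )

    def search_hits(self, query: str) -> list[tuple[int, str]]:
        """Exact normalized matches first, then substring matches; each
        group in ascending page-id order."""
        wanted = normalize_name(query)
        exact = sorted(
            pid for pid, name in self._names.items() if normalize_name(name) == wanted
        )
        fuzzy = sorted(
            pid for pid, name in self._names.items()
            if wanted in normalize_name(name) and pid not in exact
        )
        return [(pid, self._names[pid]) for pid in exact + fuzzy]

    def resolve(self, url: str) -> str:
        from urllib.parse import parse_qs, unquote, urlsplit

        parts = urlsplit(url)
        segments = parts.path.strip("/").split("/")
        if len(segments) >= 2 and segments[0] == "api":
            endpoint = segments[1]
            if endpoint == "search":
                query = parse_qs(parts.query).get("q", [None])[0]
                if query is not None:
                    return generate_search_xml(self.search_hits(unquote(query)))
            elif endpoint in ("pages", "hierarchy_entries") and len(segments) == 4:
                try:
                    key = int(segments[3].removesuffix(".xml"))
                except ValueError:
                    raise KeyError(url)
                store = self._pages if endpoint == "pages" else self._hierarchies
                if key in store:
                    return store[key]
        raise KeyError(url)


class OfflineTransport:
    """Transport backed by a :class:`FixtureRegistry`; same URL and registry
    state always yield the same body."""

    def __init__(self, registry: FixtureRegistry):
        self.registry = registry

    def get(self, url: str) -> str:
        try:
            return self.registry.resolve(url)
        except KeyError:
            raise DocumentNotFoundError(url)


def make_offline_transport(registry: FixtureRegistry) -> Transport:
    return OfflineTransport(registry)


# ---------------------------------------------------------------------------
# worked examples

NCBI = "NCBI Taxonomy"
GBIF = "GBIF Nub Taxonomy"

#: The six "bears": disparate lineages that share nothing but a vernacular
#: word, hand-encoded NCBI-style kingdom→species.  The two plants carry no
#: order-level ancestor, so the assembled taxon × rank matrix shows missing
#: cells exactly where classification data have gaps.
BEAR_LINEAGES: dict[str, list[tuple[str, str | None]]] = {
    "Ursus maritimus": [
        ("Animalia", "kingdom"), ("Chordata", "phylum"), ("Mammalia", "class"),
        ("Carnivora", "order"), ("Ursidae", "family"), ("Ursus", "genus"),
    ],
    "Phascolarctos cinereus": [
        ("Animalia", "kingdom"), ("Chordata", "phylum"), ("Mammalia", "class"),
        ("Diprotodontia", "order"), ("Phascolarctidae", "family"),
        ("Phascolarctos", "genus"),
    ],
    "Echiniscus capillatus": [
        ("Animalia", "kingdom"), ("Tardigrada", "phylum"),
        ("Heterotardigrada", "class"), ("Echiniscoidea", "order"),
        ("Echiniscidae", "family"), ("Echiniscus", "genus"),
    ],
    "Pyrrharctia isabella": [
        ("Animalia", "kingdom"), ("Arthropoda", "phylum"), ("Insecta", "class"),
        ("Lepidoptera", "order"), ("Erebidae", "family"), ("Pyrrharctia", "genus"),
    ],
    "Xerophyllum tenax": [
        ("Plantae", "kingdom"), ("Tracheophyta", "phylum"), ("Liliopsida", "class"),
        ("Melanthiaceae", "family"), ("Xerophyllum", "genus"),
    ],
    "Acanthus mollis": [
        ("Plantae", "kingdom"), ("Tracheophyta", "phylum"), ("Magnoliopsida", "class"),
        ("Acanthaceae", "family"), ("Acanthus", "genus"),
    ],
}

BEAR_PAGE_IDS: dict[str, int] = {
    "Ursus maritimus": 328581,
    "Phascolarctos cinereus": 128425,
    "Echiniscus capillatus": 512601,
    "Xerophyllum tenax": 1084211,
    "Acanthus mollis": 486661,
    "Pyrrharctia isabella": 173535,
}

#: Five invasive species with their French vernacular names and the NCBI
#: synonyms attached to the classification entries ("None" = empty list).
INVASIVE_SPECIES: dict[str, dict] = {
    "Ophiostoma ulmi": {
        "page_id": 1005021, "french": [], "synonyms": [],
        "lineage": [("Fungi", "kingdom"), ("Ascomycota", "phylum"),
                    ("Ophiostomataceae", "family"), ("Ophiostoma", "genus")],
    },
    "Eriocheir sinensis": {
        "page_id": 1021797,
        "french": ["Crabe chinois à mitaines", "Crabe chinois", "Crabe velu",
                   "crabe poilu de Shangai"],
        "synonyms": ["Eriocheir chinensis", "Eriocheir japonica sinensis"],
        "lineage": [("Animalia", "kingdom"), ("Arthropoda", "phylum"),
                    ("Varunidae", "family"), ("Eriocheir", "genus")],
    },
    "Vespula vulgaris": {
        "page_id": 1008654, "french": [], "synonyms": ["Paravespula vulgaris"],
        "lineage": [("Animalia", "kingdom"), ("Arthropoda", "phylum"),
                    ("Vespidae", "family"), ("Vespula", "genus")],
    },
    "Felis catus": {
        "page_id": 1037781, "french": ["Chat"],
        "synonyms": ["Felis domesticus", "Felis silvestris catus"],
        "lineage": [("Animalia", "kingdom"), ("Chordata", "phylum"),
                    ("Felidae", "family"), ("Felis", "genus")],
    },
    "Plasmodium relictum": {
        "page_id": 1025337, "french": ["Paludisme des oiseaux"], "synonyms": [],
        "lineage": [("Protozoa", "kingdom"), ("Apicomplexa", "phylum"),
                    ("Plasmodiidae", "family"), ("Plasmodium", "genus")],
    },
}

URSUS_PAGE_ID = 14349


def _ncbi_entry_id(page_id: int) -> int:
    return page_id * 10 + 1


def _gbif_entry_id(page_id: int) -> int:
    return page_id * 10 + 2


def build_worked_example_registry() -> FixtureRegistry:
    """The packaged offline registry behind ``--offline`` and the test suite.

    Contains the *Ursus* genus page (id 14349, NCBI + GBIF classification
    entries, synonyms only on the GBIF side), the polar bear page with a
    Vulnerable status, the six bear-list taxa with their lineages, and the
    five invasive species with French vernacular names; the search index
    resolves every scientific name.
    """
    reg = FixtureRegistry()

    ursus_ncbi = _ncbi_entry_id(URSUS_PAGE_ID)
    ursus_gbif = _gbif_entry_id(URSUS_PAGE_ID)
    reg.add_page(PageSpec(
        page_id=URSUS_PAGE_ID,
        scientific_name="Ursus",
        richness_score=87.5,
        concepts=[
            TaxonConceptEntry(ursus_ncbi, NCBI, "Ursus"),
            TaxonConceptEntry(ursus_gbif, GBIF, "Ursus"),
        ],
        data_objects=[
            DataObject("ursus-text-1", "http://purl.org/dc/dcmitype/Text",
                       mime_type="text/html", language="en",
                       attributes={"title": "Description",
                                   "description": "Bears of the genus Ursus.",
                                   "source": "Wikipedia"}),
            DataObject("ursus-img-1", "http://purl.org/dc/dcmitype/StillImage",
                       mime_type="image/jpeg",
                       attributes={"title": "Brown bear", "rights": "CC-BY"}),
        ],
        common_names=[
            CommonName("bears", "en", preferred=True),
            CommonName("ours", "fr"),
        ],
        references=["Linnaeus, C. (1758). Systema Naturae."],
    ))
    ursus_ancestors = [
        RankedName(name, rank) for name, rank in BEAR_LINEAGES["Ursus maritimus"][:-1]
    ]
    reg.add_hierarchy(HierSpec(
        entry_id=ursus_ncbi, provider=NCBI,
        taxon=RankedName("Ursus", "genus"),
        ancestors=ursus_ancestors,
        children=[
            RankedName("Ursus americanus", "species"),
            RankedName("Ursus arctos", "species"),
            RankedName("Ursus maritimus", "species"),
            RankedName("Ursus thibetanus", "species"),
        ],
        synonyms=[],  # this provider reports none for the genus
    ))
    reg.add_hierarchy(HierSpec(
        entry_id=ursus_gbif, provider=GBIF,
        taxon=RankedName("Ursus", "genus"),
        ancestors=ursus_ancestors,
        children=[RankedName("Ursus arctos", "species"),
                  RankedName("Ursus maritimus", "species")],
        synonyms=[Synonym("Thalarctos"), Synonym("Melanarctos")],
    ))

    for name, lineage in BEAR_LINEAGES.items():
        page_id = BEAR_PAGE_IDS[name]
        entry_id = _ncbi_entry_id(page_id)
        extra = {}
        if name == "Ursus maritimus":
            extra = {
                "iucn_status": "Vulnerable (VU)",
                "common_names": [CommonName("Polar Bear", "en", preferred=True),
                                 CommonName("Ours blanc", "fr")],
            }
        reg.add_page(PageSpec(
            page_id=page_id,
            scientific_name=name,
            richness_score=round(40.0 + (page_id % 50) + 0.5, 1),
            concepts=[TaxonConceptEntry(entry_id, NCBI, name)],
            **extra,
        ))
        reg.add_hierarchy(HierSpec(
            entry_id=entry_id, provider=NCBI,
            taxon=RankedName(name, "species"),
            ancestors=[RankedName(n, r) for n, r in lineage],
        ))

    for name, info in INVASIVE_SPECIES.items():
        page_id = info["page_id"]
        entry_id = _ncbi_entry_id(page_id)
        reg.add_page(PageSpec(
            page_id=page_id,
            scientific_name=name,
            richness_score=round(30.0 + (page_id % 60) + 0.5, 1),
            concepts=[TaxonConceptEntry(entry_id, NCBI, name)],
            common_names=([CommonName(n, "fr") for n in info["french"]]
                          + [CommonName(f"{name} (common)", "en")]),
            synonyms=[Synonym(s) for s in info["synonyms"]],
        ))
        reg.add_hierarchy(HierSpec(
            entry_id=entry_id, provider=NCBI,
            taxon=RankedName(name, "species"),
            ancestors=[RankedName(n, r) for n, r in info["lineage"]],
            synonyms=[Synonym(s) for s in info["synonyms"]],
        ))

    return reg


# ---------------------------------------------------------------------------
# random generation


def random_taxonomy(seed: int, n_tips: int, n_ranks: int,
                    missing_prob: float = 0.0,
                    provider: str = "Synthetic Taxonomy") -> list[HierSpec]:
    """A reproducible random classification: ``n_tips`` terminal taxa over
    ``n_ranks`` ranks, sharing ancestors through random attachment so
    nontrivial topology arises; each non-terminal rank of each taxon is
    independently missing with ``missing_prob``.
    """
    if n_tips < 1 or n_ranks < 1:
        raise ContractError("n_tips and n_ranks must be >= 1")
    if not 0.0 <= missing_prob <= 1.0:
        raise ContractError("missing_prob must lie in [0, 1]")
    rng = random.Random(seed)
    ranks = (list(LINNAEAN_RANKS[:n_ranks]) if n_ranks <= len(LINNAEAN_RANKS)
             else [f"level_{i}" for i in range(n_ranks)])

    counter = [0]

    def fresh(depth: int) -> str:
        counter[0] += 1
        return f"{ranks[depth]}_{counter[0]:03d}"

    full_paths: list[list[str]] = [[fresh(d) for d in range(n_ranks)]]
    for _ in range(n_tips - 1):
        donor = rng.choice(full_paths)
        attach = rng.randrange(n_ranks)  # depth of the first fresh level
        full_paths.append(donor[:attach] + [fresh(d) for d in range(attach, n_ranks)])

    specs = []
    for i, path in enumerate(full_paths):
        keep = [rng.random() >= missing_prob for _ in range(n_ranks - 1)] + [True]
        ancestors = [
            RankedName(name, ranks[d])
            for d, name in enumerate(path[:-1]) if keep[d]
        ]
        specs.append(HierSpec(
            entry_id=i + 1, provider=provider,
            taxon=RankedName(path[-1], ranks[-1]),
            ancestors=ancestors,
        ))
    return specs


_WORDS = ("lorem", "ipsum", "dolor", "amet", "felis", "ursus", "aqua",
          "silva", "montis", "borealis", "écharpe", "niño")


def _rand_text(rng: random.Random, n_words: int = 3) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(n_words))


_DCMI = "http://purl.org/dc/dcmitype/"
_TYPE_URIS = (_DCMI + "Text", _DCMI + "StillImage", _DCMI + "Sound",
              _DCMI + "MovingImage", _DCMI + "Dataset")
_LANGS = ("en", "fr", "de", "es", "und")


def random_page_spec(rng: random.Random, page_id: int | None = None) -> PageSpec:
    """A random but always-valid PageSpec, for round-trip and conservation
    property tests."""
    page_id = page_id if page_id is not None else rng.randrange(1, 10**7)
    providers = rng.sample([NCBI, GBIF, "ITIS", "WoRMS", "Index Fungorum"],
                           k=rng.randrange(0, 4))
    return PageSpec(
        page_id=page_id,
        scientific_name=_rand_text(rng, 2).title(),
        richness_score=(round(rng.uniform(0, 100), 2)
                        if rng.random() < 0.8 else None),
        concepts=[
            TaxonConceptEntry(page_id * 100 + i, prov, _rand_text(rng, 1))
            for i, prov in enumerate(providers, start=1)
        ],
        data_objects=[
            DataObject(
                object_id=f"obj-{page_id}-{i}",
                data_type_uri=rng.choice(_TYPE_URIS),
                mime_type=rng.choice(["text/html", "image/jpeg", None]),
                language=rng.choice([None, "en", "fr"]),
                attributes={"title": _rand_text(rng),
                            "description": _rand_text(rng, 5)},
            )
            for i in range(rng.randrange(0, 5))
        ],
        common_names=[
            CommonName(_rand_text(rng, 2), rng.choice(_LANGS),
                       preferred=rng.random() < 0.2)
            for _ in range(rng.randrange(0, 5))
        ],
        references=[_rand_text(rng, 6) for _ in range(rng.randrange(0, 4))],
        synonyms=[Synonym(_rand_text(rng, 2).title())
                  for _ in range(rng.randrange(0, 3))],
        iucn_status=rng.choice([None, "Least Concern (LC)", "Endangered (EN)",
                                "Vulnerable (VU)"]),
    )


def random_hier_spec(rng: random.Random, entry_id: int | None = None) -> HierSpec:
    entry_id = entry_id if entry_id is not None else rng.randrange(1, 10**7)
    depth = rng.randrange(0, 6)
    names = rng.sample(
        [f"{w.title()}{i}" for i, w in enumerate(_WORDS)], k=depth + 1
    )
    ranks = list(LINNAEAN_RANKS[:depth]) + [None]
    ancestors = [
        RankedName(names[d], ranks[d] if rng.random() < 0.8 else None,
                   entry_id=rng.randrange(1, 10**6) if rng.random() < 0.5 else None)
        for d in range(depth)
    ]
    return HierSpec(
        entry_id=entry_id,
        provider=rng.choice([NCBI, GBIF, "ITIS"]),
        taxon=RankedName(names[depth],
                         rng.choice(["species", "genus", None])),
        ancestors=ancestors,
        children=[RankedName(_rand_text(rng, 2).title(), "species")
                  for _ in range(rng.randrange(0, 4))],
        synonyms=[Synonym(_rand_text(rng, 2).title())
                  for _ in range(rng.randrange(0, 3))],
    )
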