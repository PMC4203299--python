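"""Typed records for the EOL v1.0 XML dialect and parsers from text to records.

The dialect
-----------
Each response is a ``<response>`` document.  Search responses hold
``<entry><id/><title/></entry>`` hits; taxon pages hold a single
``<taxonConcept>``; provider classification pages hold a single
``<hierarchyEntry>``.  Element names are Darwin-Core flavoured
(``taxonConceptEntry``, ``dataObject``, ``commonName``, ``synonym``,
``ancestor``) and documents are UTF-8.  The full element inventory is what
:mod:`eolkit.fixtures` emits; unknown elements are skipped with a debug log so
richer documents still parse.

Records are plain frozen-ish dataclasses with value equality, which makes
generate→parse round-trips directly assertable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from lxml import etree

from .errors import ContractError, DialectError, ParseError

logger = logging.getLogger(__name__)

#: Media-class kinds recognised from dcmitype URIs; anything else is "Other".
DATA_TYPE_KINDS = ("Text", "StillImage", "Sound", "MovingImage")

_KIND_BY_TOKEN = {k.lower(): k for k in DATA_TYPE_KINDS}


def classify_data_type(uri: str) -> str:
    """Map a dcmitype-style URI to a media kind by its trailing token.

    The comparison is case-insensitive on the last path/fragment segment;
    unknown tokens classify as ``"Other"`` rather than erroring.
    """
    token = uri.rstrip("/").rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    return _KIND_BY_TOKEN.get(token.lower(), "Other")


@dataclass
class SearchHit:
    page_id: int
    matched_name: str

    def __post_init__(self):
        if self.page_id <= 0:
            raise ContractError(f"page_id must be positive, got {self.page_id}")
        if not self.matched_name:
            raise ContractError("matched_name must be non-empty")


@dataclass
class TaxonConceptEntry:
    """One provider's classification entry attached to an EOL page."""

    entry_id: int
    provider: str
    canonical_name: str

    def __post_init__(self):
        if self.entry_id <= 0:
            raise ContractError(f"entry_id must be positive, got {self.entry_id}")
        if not self.provider:
            raise ContractError("provider must be non-empty")


@dataclass
class DataObject:
    """An individually accessioned media item (text block, image, sound...).

    ``data_type`` is the classified kind (Text/StillImage/Sound/MovingImage/
    Other); ``data_type_uri`` keeps the raw URI.  ``attributes`` holds the
    remaining fields (title, description, rights, source, ...) in document
    order.
    """

    object_id: str
    data_type_uri: str
    mime_type: str | None = None
    language: str | None = None
    attributes: dict = field(default_factory=dict)

    @property
    def data_type(self) -> str:
        return classify_data_type(self.data_type_uri)


@dataclass
class CommonName:
    name: str
    language: str = "und"
    preferred: bool = False

    def __post_init__(self):
        if not self.name:
            raise ContractError("common name must be non-empty")
        if not self.language:
            self.language = "und"


@dataclass
class Synonym:
    name: str
    relationship: str = "synonym"

    def __post_init__(self):
        if not self.name:
            raise ContractError("synonym name must be non-empty")


@dataclass
class EOLPage:
    """A parsed per-taxon EOL page."""

    page_id: int
    scientific_name: str
    richness_score: float | None = None
    concepts: list[TaxonConceptEntry] = field(default_factory=list)
    data_objects: list[DataObject] = field(default_factory=list)
    common_names: list[CommonName] = field(default_factory=list)
    references: list[str] = field(default_factory=list)
    synonyms: list[Synonym] = field(default_factory=list)
    iucn_status: str | None = None

    def __post_init__(self):
        if self.page_id <= 0:
            raise ContractError(f"page_id must be positive, got {self.page_id}")
        if self.richness_score is not None and not (0.0 <= self.richness_score <= 100.0):
            raise ContractError(
                f"richness score must lie in [0, 100], got {self.richness_score}"
            )
        entry_ids = [c.entry_id for c in self.concepts]
        if len(entry_ids) != len(set(entry_ids)):
            raise ContractError("concept hierarchy-entry IDs must be unique on a page")
        object_ids = [o.object_id for o in self.data_objects]
        if len(object_ids) != len(set(object_ids)):
            raise ContractError("data object IDs must be unique on a page")

    def providers(self) -> list[str]:
        """Distinct providers with a concept entry, in page order."""
        seen: dict[str, None] = {}
        for c in self.concepts:
            seen.setdefault(c.provider, None)
        return list(seen)


@dataclass
class RankedName:
    """A taxon name with an optional Linnaean rank and provider entry id."""

    name: str
    rank: str | None = None
    entry_id: int | None = None

    def __post_init__(self):
        if not self.name:
            raise ContractError("taxon name must be non-empty")


@dataclass
class HierarchyPage:
    """A provider classification page: one ranked taxon with its ancestors
    (most-inclusive first), children and synonyms."""

    entry_id: int
    provider: str
    taxon: RankedName
    ancestors: list[RankedName] = field(default_factory=list)
    children: list[RankedName] = field(default_factory=list)
    synonyms: list[Synonym] = field(default_factory=list)

    def __post_init__(self):
        if self.entry_id <= 0:
            raise ContractError(f"entry_id must be positive, got {self.entry_id}")
        names = [a.name for a in self.ancestors]
        if len(names) != len(set(names)):
            raise ContractError("ancestor names must be unique within a page")
        if self.taxon.name in names:
            raise ContractError(
                f"taxon {self.taxon.name!r} must not appear among its own ancestors"
            )


# ---------------------------------------------------------------------------
# parsing


def _root(doc: str | bytes) -> etree._Element:
    if isinstance(doc, str):
        doc = doc.encode("utf-8")
    try:
        root = etree.fromstring(doc)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    if root.tag != "response":
        raise DialectError(f"expected <response> root, found <{root.tag}>")
    return root


def _text(elem: etree._Element, tag: str, required: bool = False) -> str | None:
    child = elem.find(tag)
    if child is None or child.text is None:
        if required:
            raise DialectError(f"<{elem.tag}> is missing required <{tag}>")
        return None
    return child.text


def parse_search_response(doc: str | bytes) -> list[SearchHit]:
    """Parse a search response into hits in document order."""
    root = _root(doc)
    hits = []
    for elem in root:
        if elem.tag == "entry":
            hits.append(
                SearchHit(
                    page_id=int(_text(elem, "id", required=True)),
                    matched_name=_text(elem, "title", required=True),
                )
            )
        elif elem.tag is not etree.Comment:
            raise DialectError(f"unexpected <{elem.tag}> in search response")
    return hits


_PAGE_TAGS = {
    "taxonConceptID", "scientificName", "richnessScore", "iucnStatus",
    "taxonConceptEntry", "dataObject", "commonName", "reference", "synonym",
}


def parse_eol_page(doc: str | bytes) -> EOLPage:
    """Parse a taxon page.  Missing optional sections yield empty lists /
    absent score; a recognised element is never silently dropped."""
    root = _root(doc)
    concept = root.find("taxonConcept")
    if concept is None:
        raise DialectError("page response is missing <taxonConcept>")

    page_id = _text(concept, "taxonConceptID", required=True)
    name = _text(concept, "scientificName", required=True)
    score = _text(concept, "richnessScore")

    concepts, objects, names, refs, syns = [], [], [], [], []
    iucn = _text(concept, "iucnStatus")
    for elem in concept:
        if elem.tag == "taxonConceptEntry":
            concepts.append(
                TaxonConceptEntry(
                    entry_id=int(_text(elem, "identifier", required=True)),
                    provider=_text(elem, "provider", required=True),
                    canonical_name=_text(elem, "canonicalName") or "",
                )
            )
        elif elem.tag == "dataObject":
            objects.append(_parse_data_object(elem))
        elif elem.tag == "commonName":
            names.append(
                CommonName(
                    name=elem.text or "",
                    language=elem.get("language") or "und",
                    preferred=elem.get("preferred", "false") == "true",
                )
            )
        elif elem.tag == "reference":
            refs.append(elem.text or "")
        elif elem.tag == "synonym":
            syns.append(
                Synonym(name=elem.text or "", relationship=elem.get("relationship", "synonym"))
            )
        elif elem.tag not in _PAGE_TAGS and elem.tag is not etree.Comment:
            logger.debug("ignoring unknown element <%s> on page %s", elem.tag, page_id)

    return EOLPage(
        page_id=int(page_id),
        scientific_name=name,
        richness_score=None if score is None else float(score),
        concepts=concepts,
        data_objects=objects,
        common_names=names,
        references=refs,
        synonyms=syns,
        iucn_status=iucn,
    )


_OBJECT_TAGS = {"dataObjectID", "dataType", "mimeType", "language"}


def _parse_data_object(elem: etree._Element) -> DataObject:
    attributes = {}
    for child in elem:
        if child.tag not in _OBJECT_TAGS and child.tag is not etree.Comment:
            attributes[child.tag] = child.text or ""
    return DataObject(
        object_id=_text(elem, "dataObjectID", required=True),
        data_type_uri=_text(elem, "dataType", required=True),
        mime_type=_text(elem, "mimeType"),
        language=_text(elem, "language"),
        attributes=attributes,
    )


def _parse_ranked_name(elem: etree._Element) -> RankedName:
    entry_id = _text(elem, "entryID")
    return RankedName(
        name=_text(elem, "scientificName", required=True),
        rank=_text(elem, "taxonRank"),
        entry_id=None if entry_id is None else int(entry_id),
    )


_HIER_TAGS = {"entryID", "provider", "scientificName", "taxonRank",
              "ancestor", "child", "synonym"}


def parse_hierarchy_page(doc: str | bytes) -> HierarchyPage:
    """Parse a provider classification page.

    Ancestors come back in document order, which the dialect pins as
    most-inclusive → least-inclusive; ranks are kept verbatim and may be
    absent (unranked levels).
    """
    root = _root(doc)
    entry = root.find("hierarchyEntry")
    if entry is None:
        raise DialectError("hierarchy response is missing <hierarchyEntry>")

    entry_id = int(_text(entry, "entryID", required=True))
    taxon = RankedName(
        name=_text(entry, "scientificName", required=True),
        rank=_text(entry, "taxonRank"),
        entry_id=entry_id,
    )
    ancestors, children, syns = [], [], []
    for elem in entry:
        if elem.tag == "ancestor":
            ancestors.append(_parse_ranked_name(elem))
        elif elem.tag == "child":
            children.append(_parse_ranked_name(elem))
        elif elem.tag == "synonym":
            syns.append(
                Synonym(name=elem.text or "", relationship=elem.get("relationship", "synonym"))
            )
        elif elem.tag not in _HIER_TAGS and elem.tag is not etree.Comment:
            logger.debug("ignoring unknown element <%s> on entry %s", elem.tag, entry_id)

    return HierarchyPage(
        entry_id=entry_id,
        provider=_text(entry, "provider", required=True),
        taxon=taxon,
        ancestors=ancestors,
        children=children,
        synonyms=syns,
    )
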