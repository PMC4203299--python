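"""EOL-dialect API client: URL construction, transports, and downloads.

URLs follow the v1.0 XML dialect::

    http://eol.org/api/search/1.0.xml?q=<query>
    http://eol.org/api/pages/1.0/<id>.xml?<content-class params>
    http://eol.org/api/hierarchy_entries/1.0/<id>.xml

The transport is pluggable: :class:`HttpTransport` performs live GETs, while
the offline transport built by :func:`eolkit.fixtures.make_offline_transport`
serves packaged fixture XML so the whole pipeline runs with no network.
"""

from __future__ import annotations

import logging
import os
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Protocol
from urllib.parse import parse_qsl, quote, urlsplit, urlunsplit

from .errors import (
    ContractError,
    DocumentNotFoundError,
    ProviderNotFoundError,
    ResolutionError,
    TransportError,
)
from .page_model import EOLPage, HierarchyPage, SearchHit, parse_eol_page, \
    parse_hierarchy_page, parse_search_response

logger = logging.getLogger(__name__)

BASE_URL = "http://eol.org"
API_VERSION = "1.0"  # the dialect this client speaks; later versions differ

#: Content classes requested on every page download, so extractors never need
#: a second fetch for names, synonyms, references or media.
DEFAULT_PAGE_PARAMS = (
    ("common_names", "true"),
    ("synonyms", "true"),
    ("references", "true"),
    ("details", "true"),
)

#: Environment variable consulted for the API key when none is given.
API_KEY_ENV = "EOL_API_KEY"


class Endpoint(str, Enum):
    SEARCH = "search"
    PAGES = "pages"
    HIERARCHY_ENTRIES = "hierarchy_entries"


def normalize_name(name: str) -> str:
    """Canonical form for taxon-name comparison: trim, collapse internal
    whitespace, case-fold.  Authority strings are NOT stripped."""
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class ApiRequest:
    """A single API call, prior to rendering.

    ``endpoint=search`` requires ``query`` and no ``key``; the id-addressed
    endpoints require ``key`` and no ``query``.
    """

    endpoint: Endpoint
    key: int | None = None
    query: str | None = None
    params: tuple[tuple[str, str], ...] = ()
    api_key: str | None = None

    def __post_init__(self):
        if self.endpoint == Endpoint.SEARCH:
            if not self.query or self.key is not None:
                raise ContractError("search requests need a query and no key")
        else:
            if self.query is not None or self.key is None:
                raise ContractError(
                    f"{self.endpoint.value} requests need a key and no query"
                )
            if self.key <= 0:
                raise ContractError(f"page/entry key must be positive, got {self.key}")


def search_request(query: str) -> ApiRequest:
    return ApiRequest(Endpoint.SEARCH, query=query)


def page_request(page_id: int) -> ApiRequest:
    return ApiRequest(Endpoint.PAGES, key=page_id, params=DEFAULT_PAGE_PARAMS)


def hierarchy_request(entry_id: int) -> ApiRequest:
    return ApiRequest(Endpoint.HIERARCHY_ENTRIES, key=entry_id)


def build_api_url(request: ApiRequest) -> str:
    """Render a request to its URL.  Pure and deterministic: equal requests
    render equal strings; declared parameter order is kept, api key last."""
    params = list(request.params)
    if request.endpoint == Endpoint.SEARCH:
        url = f"{BASE_URL}/api/search/{API_VERSION}.xml"
        params = [("q", request.query)] + params
    else:
        url = f"{BASE_URL}/api/{request.endpoint.value}/{API_VERSION}/{request.key}.xml"
    if request.api_key:
        params.append(("key", request.api_key))
    if params:
        url += "?" + "&".join(f"{k}={quote(str(v), safe='')}" for k, v in params)
    return url


def attach_api_key(url: str, key: str) -> str:
    """Append exactly one ``key=`` parameter; idempotent for the same key.

    An empty key is a no-op with a logged warning (the live service treats
    keyless calls as anonymous).
    """
    if not key:
        logger.warning("empty API key ignored for %s", url)
        return url
    parts = urlsplit(url)
    pairs = parse_qsl(parts.query, keep_blank_values=True)
    if ("key", key) in pairs:
        return url
    pairs = [(k, v) for k, v in pairs if k != "key"] + [("key", key)]
    query = "&".join(f"{k}={quote(v, safe='')}" for k, v in pairs)
    return urlunsplit((parts.scheme, parts.netloc, parts.path, query, parts.fragment))


def resolve_api_key(cli_value: str | None = None,
                    config_path: str | Path | None = None) -> str | None:
    """API key lookup: explicit value > environment > ``key=value`` config file."""
    if cli_value:
        return cli_value
    env = os.environ.get(API_KEY_ENV)
    if env:
        return env
    if config_path and Path(config_path).exists():
        for line in Path(config_path).read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                if k.strip() == "key" and v.strip():
                    return v.strip()
    return None


class Transport(Protocol):
    """Given a rendered URL, return the document body or raise a typed
    failure (``DocumentNotFoundError``, ``TransportError``)."""

    def get(self, url: str) -> str: ...


class HttpTransport:
    """Live HTTP GET transport (stdlib urllib; single configurable timeout,
    no retries — failures are surfaced, never silently retried)."""

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def get(self, url: str) -> str:
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return resp.read().decode("utf-8")
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise DocumentNotFoundError(url) from exc
            raise TransportError(f"HTTP {exc.code} for {url}") from exc
        except urllib.error.URLError as exc:
            raise TransportError(f"network failure for {url}: {exc.reason}") from exc


def fetch_document(url: str, transport: Transport) -> str:
    """Fetch raw XML text exactly as served; no parsing happens here."""
    try:
        body = transport.get(url)
    except DocumentNotFoundError:
        logger.info("GET %s -> not found", url)
        raise
    except TransportError:
        logger.info("GET %s -> transport failure", url)
        raise
    logger.info("GET %s -> %d bytes", url, len(body))
    return body


class PageSet:
    """Ordered collection of :class:`EOLPage` keyed by EOL page id, with a
    provenance note (URL or fixture id) per entry."""

    def __init__(self):
        self._pages: dict[int, EOLPage] = {}
        self._provenance: dict[int, str] = {}

    def add(self, page: EOLPage, provenance: str = "") -> None:
        if page.page_id in self._pages:
            raise ContractError(f"duplicate page id {page.page_id} in PageSet")
        self._pages[page.page_id] = page
        self._provenance[page.page_id] = provenance

    def __iter__(self) -> Iterator[EOLPage]:
        return iter(self._pages.values())

    def __len__(self) -> int:
        return len(self._pages)

    def __getitem__(self, page_id: int) -> EOLPage:
        return self._pages[page_id]

    def __contains__(self, page_id: int) -> bool:
        return page_id in self._pages

    def page_ids(self) -> list[int]:
        return list(self._pages)

    def provenance(self, page_id: int) -> str:
        return self._provenance[page_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PageSet):
            return NotImplemented
        return list(self._pages.items()) == list(other._pages.items())


class HierarchySet:
    """Ordered collection of :class:`HierarchyPage`, all from one provider,
    keyed by entry id."""

    def __init__(self, provider: str):
        self.provider = provider
        self._pages: dict[int, HierarchyPage] = {}

    def add(self, page: HierarchyPage) -> None:
        if page.provider != self.provider:
            raise ContractError(
                f"page provider {page.provider!r} does not match set provider "
                f"{self.provider!r}"
            )
        if page.entry_id in self._pages:
            raise ContractError(f"duplicate entry id {page.entry_id} in HierarchySet")
        self._pages[page.entry_id] = page

    def __iter__(self) -> Iterator[HierarchyPage]:
        return iter(self._pages.values())

    def __len__(self) -> int:
        return len(self._pages)

    def __getitem__(self, entry_id: int) -> HierarchyPage:
        return self._pages[entry_id]

    def entry_ids(self) -> list[int]:
        return list(self._pages)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HierarchySet):
            return NotImplemented
        return (self.provider == other.provider
                and list(self._pages.items()) == list(other._pages.items()))


def _fetch_pages(ids: list[int], transport: Transport,
                 api_key: str | None) -> tuple[dict[int, tuple[str, str]], dict]:
    """Fetch every id, returning {id: (url, body)} and {id: reason} failures."""
    bodies: dict[int, tuple[str, str]] = {}
    failures: dict[int, str] = {}
    for page_id in ids:
        url = build_api_url(page_request(page_id))
        if api_key:
            url = attach_api_key(url, api_key)
        try:
            bodies[page_id] = (url, fetch_document(url, transport))
        except (DocumentNotFoundError, TransportError) as exc:
            failures[page_id] = str(exc)
    return bodies, failures


def download_eol_pages(ids: list[int], transport: Transport, *,
                       to_file: bool = False, dir: str | Path | None = None,
                       api_key: str | None = None) -> PageSet | list[Path]:
    """Download taxon pages by EOL page id.

    With ``to_file=False`` returns a :class:`PageSet` in input order; with
    ``to_file=True`` writes one ``eol_page_<id>.xml`` per page into ``dir``
    and returns the paths.  Every id is attempted; if any fails, a
    :class:`ResolutionError` lists all failing ids and partial results are
    discarded.
    """
    if not ids:
        raise ContractError("ids must be non-empty")
    if any(i <= 0 for i in ids):
        raise ContractError(f"page ids must be positive: {ids}")
    if to_file and dir is None:
        raise ContractError("to_file=True requires a target dir")

    bodies, failures = _fetch_pages(list(ids), transport, api_key)
    if failures:
        raise ResolutionError(failures)

    if to_file:
        out_dir = Path(dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for page_id in ids:
            path = out_dir / f"eol_page_{page_id}.xml"
            path.write_text(bodies[page_id][1], encoding="utf-8")
            paths.append(path)
        return paths

    pages = PageSet()
    for page_id in ids:
        url, body = bodies[page_id]
        pages.add(parse_eol_page(body), provenance=url)
    return pages


def resolve_names(names: list[str], transport: Transport, *,
                  exact: bool = False) -> tuple[dict[str, SearchHit], dict]:
    """Resolve taxon names to search hits.

    Exact mode requires a whole-string match under :func:`normalize_name`;
    fuzzy mode takes the first hit.  Returns (resolved, failures) keyed by
    the query name, preserving input order in ``resolved``.
    """
    resolved: dict[str, SearchHit] = {}
    failures: dict[str, str] = {}
    for name in names:
        url = build_api_url(search_request(name))
        try:
            hits = parse_search_response(fetch_document(url, transport))
        except (DocumentNotFoundError, TransportError) as exc:
            failures[name] = str(exc)
            continue
        if exact:
            wanted = normalize_name(name)
            match = next((h for h in hits if normalize_name(h.matched_name) == wanted), None)
            if match is None:
                failures[name] = "no exact whole-string match"
                continue
            resolved[name] = match
        else:
            if not hits:
                failures[name] = "no search hits"
                continue
            resolved[name] = hits[0]
    return resolved, failures


def download_searched_taxa(names: list[str], transport: Transport, *,
                           exact: bool = False, to_file: bool = False,
                           dir: str | Path | None = None,
                           api_key: str | None = None) -> PageSet | list[Path]:
    """Resolve each name through the search endpoint, then download its page.

    Names that fail to resolve are collected and reported together in one
    :class:`ResolutionError`; nothing partial is returned.
    """
    if not names:
        raise ContractError("names must be non-empty")
    resolved, failures = resolve_names(list(names), transport, exact=exact)
    if failures:
        logger.warning("unresolved names: %s", sorted(failures))
        raise ResolutionError(failures)
    ids = [hit.page_id for hit in resolved.values()]
    return download_eol_pages(ids, transport, to_file=to_file, dir=dir, api_key=api_key)


def download_hierarchy(source: PageSet, database: str, transport: Transport, *,
                       to_file: bool = False, dir: str | Path | None = None,
                       api_key: str | None = None) -> HierarchySet | list[Path]:
    """Follow each page's concept entry for ``database`` and download the
    provider classification page.  Output order = input order."""
    if to_file and dir is None:
        raise ContractError("to_file=True requires a target dir")

    entry_ids = []
    for page in source:
        entry = next((c for c in page.concepts if c.provider == database), None)
        if entry is None:
            raise ProviderNotFoundError(page.scientific_name, database, page.providers())
        entry_ids.append(entry.entry_id)

    bodies: dict[int, str] = {}
    failures: dict[int, str] = {}
    for entry_id in entry_ids:
        url = build_api_url(hierarchy_request(entry_id))
        if api_key:
            url = attach_api_key(url, api_key)
        try:
            bodies[entry_id] = fetch_document(url, transport)
        except (DocumentNotFoundError, TransportError) as exc:
            failures[entry_id] = str(exc)
    if failures:
        raise ResolutionError(failures)

    if to_file:
        out_dir = Path(dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for entry_id in entry_ids:
            path = out_dir / f"hier_page_{entry_id}.xml"
            path.write_text(bodies[entry_id], encoding="utf-8")
            paths.append(path)
        return paths

    hset = HierarchySet(provider=database)
    for entry_id in entry_ids:
        hset.add(parse_hierarchy_page(bodies[entry_id]))
    return hset
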