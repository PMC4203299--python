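"""End-user tables extracted from downloaded taxon pages.

All functions return a :class:`pandas.DataFrame` whose first two columns are
``taxon_name`` and ``eol_page_id`` (one row per input page for per-taxon
tables, in input order).  Missing values are typed-absent (NaN/None) in
memory and render as the token ``"NA"`` through :func:`write_table`.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd

from .api_client import PageSet
from .errors import ContractError
from .page_model import DATA_TYPE_KINDS, EOLPage

#: The ten conservation-status codes, from no-data through extinct.
IUCN_CODES = ("NA", "NE", "DD", "LC", "NT", "VU", "EN", "CR", "EW", "EX")

_IUCN_NAMES = {
    "not available": "NA",
    "not evaluated": "NE",
    "data deficient": "DD",
    "least concern": "LC",
    "near threatened": "NT",
    "vulnerable": "VU",
    "endangered": "EN",
    "critically endangered": "CR",
    "extinct in the wild": "EW",
    "extinct": "EX",
}


def write_table(table: pd.DataFrame, path: str | Path, *, fmt: str = "csv",
                na_rep: str = "NA") -> None:
    """Write a result table as UTF-8 CSV/TSV with a header row; missing
    values render as ``na_rep`` (default the R-style token ``"NA"``)."""
    if fmt not in ("csv", "tsv"):
        raise ContractError(f"format must be csv or tsv, got {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    table.to_csv(path, sep=sep, index=False, na_rep=na_rep, encoding="utf-8")


def _base_columns(pages: PageSet) -> dict:
    return {
        "taxon_name": [p.scientific_name for p in pages],
        "eol_page_id": [p.page_id for p in pages],
    }


def get_richness_scores(pages: PageSet) -> pd.DataFrame:
    """One row per page with the server-computed 0–100 richness score
    (absent scores stay missing)."""
    data = _base_columns(pages)
    data["richness_score"] = [p.richness_score for p in pages]
    return pd.DataFrame(data)


def relative_richness(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize richness by the mean over non-missing scores.

    Adds a ``relative_richness`` column (score / mean); by construction the
    new column averages to 1.0 over non-missing entries, so a value above 1
    means better-than-average coverage in the queried group.
    """
    if "richness_score" not in table.columns:
        raise ContractError("table has no richness_score column")
    scores = pd.to_numeric(table["richness_score"], errors="coerce")
    if scores.notna().sum() == 0:
        raise ContractError("all richness scores are missing; cannot standardize")
    out = table.copy()
    out["relative_richness"] = scores / scores.mean()
    return out


def data_object_overview(pages: PageSet) -> pd.DataFrame:
    """Per-page counts of media objects by kind.

    Columns are the union of kinds observed anywhere in the set, in the
    canonical kind order (Text, StillImage, Sound, MovingImage, then others
    alphabetically); row sums equal each page's object count.
    """
    observed = {kind for p in pages for kind in (o.data_type for o in p.data_objects)}
    ordered = [k for k in DATA_TYPE_KINDS if k in observed]
    ordered += sorted(observed - set(DATA_TYPE_KINDS))
    data = _base_columns(pages)
    for kind in ordered:
        data[kind] = [sum(o.data_type == kind for o in p.data_objects) for p in pages]
    return pd.DataFrame(data)


def gather_data_object_information(page: EOLPage,
                                   object_id: str | None = None) -> pd.DataFrame:
    """Long-format (field, value) listing for one media object, or for all
    objects on the page (with an ``object_id`` column) when none is named."""
    if object_id is not None:
        matches = [o for o in page.data_objects if o.object_id == object_id]
        if not matches:
            raise ContractError(
                f"page {page.page_id} has no data object {object_id!r}"
            )
        objects = matches
        rows = [(f, v) for o in objects for f, v in _object_fields(o)]
        return pd.DataFrame(rows, columns=["field", "value"])
    rows = [(o.object_id, f, v) for o in page.data_objects for f, v in _object_fields(o)]
    return pd.DataFrame(rows, columns=["object_id", "field", "value"])


def _object_fields(o) -> list[tuple[str, str]]:
    fields = [
        ("data_type", o.data_type),
        ("data_type_uri", o.data_type_uri),
        ("mime_type", o.mime_type),
        ("language", o.language),
    ]
    fields += list(o.attributes.items())
    return [(f, v) for f, v in fields if v is not None]


def get_common_names(pages: PageSet, mode: str = "counts") -> pd.DataFrame:
    """Vernacular names, either counted per language or listed in detail.

    ``counts``: one row per page, one integer column per language tag seen
    anywhere in the set (raw tags, alphabetical).  ``detail``: one row per
    (page, name) with the name, its language tag and the preferred flag.
    """
    _check_mode(mode)
    if mode == "counts":
        languages = sorted({cn.language for p in pages for cn in p.common_names})
        data = _base_columns(pages)
        for lang in languages:
            data[lang] = [sum(cn.language == lang for cn in p.common_names) for p in pages]
        return pd.DataFrame(data)
    rows = [
        (p.scientific_name, p.page_id, cn.name, cn.language, cn.preferred)
        for p in pages for cn in p.common_names
    ]
    return pd.DataFrame(
        rows, columns=["taxon_name", "eol_page_id", "common_name", "language", "preferred"]
    )


def get_references(pages: PageSet, mode: str = "counts") -> pd.DataFrame:
    """Bibliographic references per page, as counts or a detailed list."""
    _check_mode(mode)
    if mode == "counts":
        data = _base_columns(pages)
        data["n_references"] = [len(p.references) for p in pages]
        return pd.DataFrame(data)
    rows = [(p.scientific_name, p.page_id, r) for p in pages for r in p.references]
    return pd.DataFrame(rows, columns=["taxon_name", "eol_page_id", "reference"])


def _check_mode(mode: str) -> None:
    if mode not in ("counts", "detail"):
        raise ContractError(f"mode must be 'counts' or 'detail', got {mode!r}")


def parse_iucn_code(text: str) -> str | None:
    """Map a status string like ``"Vulnerable (VU)"`` to its code.

    Tries a parenthesised code first, then the full category name
    (longest-name-first so "critically endangered" beats "endangered");
    returns None when unrecognised.
    """
    m = re.search(r"\(([A-Za-z]{2})\)", text)
    if m and m.group(1).upper() in IUCN_CODES:
        return m.group(1).upper()
    stripped = text.strip()
    if stripped.upper() in IUCN_CODES:
        return stripped.upper()
    folded = stripped.casefold()
    for name in sorted(_IUCN_NAMES, key=len, reverse=True):
        if name in folded:
            return _IUCN_NAMES[name]
    return None


def _page_iucn(page: EOLPage) -> str:
    text = page.iucn_status
    if text is None:
        # fall back to an IUCN-attributed text object, if the page carries one
        for o in page.data_objects:
            source = " ".join(
                str(v) for k, v in o.attributes.items() if k in ("source", "rights", "title")
            )
            if o.data_type == "Text" and "iucn" in source.casefold():
                text = o.attributes.get("description", "")
                break
    if text is None:
        return "NA"
    code = parse_iucn_code(text)
    if code is None:
        warnings.warn(f"unrecognized conservation status {text!r}; recording NA")
        return "NA"
    return code


def get_iucn_status(pages: PageSet) -> pd.DataFrame:
    """Conservation status per page as one of the ten codes; pages with no
    status element (and no IUCN-attributed text object) record ``"NA"``."""
    data = _base_columns(pages)
    data["iucn_status"] = [_page_iucn(p) for p in pages]
    return pd.DataFrame(data)


def provider_count(pages: PageSet) -> pd.DataFrame:
    """Pages covered per classification provider, sorted by count descending
    then name ascending.  A provider listed twice on one page counts once —
    this measures page coverage, not entry volume."""
    counts: dict[str, int] = {}
    for p in pages:
        for provider in p.providers():
            counts[provider] = counts.get(provider, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["provider", "n_pages"])


def best_provider(pages: PageSet) -> str:
    """The provider covering the most pages (ties broken alphabetically)."""
    table = provider_count(pages)
    if table.empty:
        raise ContractError("no concept entries in the page set")
    return table["provider"].iloc[0]
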