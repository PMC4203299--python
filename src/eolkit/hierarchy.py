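"""Provider classification-page operations and EOL↔provider matching.

Synonyms, parentage and offspring are lossless projections of a
:class:`HierarchyPage`; the matching functions bridge the two identifier
spaces (EOL page ids vs provider entry ids) by joining on normalized taxon
names — names are trimmed, whitespace-collapsed and case-folded, but
authority strings are never stripped (silently dropping authorships can
create false matches, so mismatches are surfaced instead).
"""

from __future__ import annotations

import logging

import pandas as pd

from .api_client import (
    HierarchySet,
    PageSet,
    Transport,
    normalize_name,
    resolve_names,
)
from .errors import AmbiguityError, ContractError
from .page_model import HierarchyPage, RankedName, Synonym

__all__ = [
    "HierarchyPage", "HierarchySet", "RankedName", "Synonym",
    "gather_synonyms", "taxon_parents", "taxon_children",
    "match_taxa_to_eol_id", "match_hier_page_to_eol_data",
    "vernacular_synonym_report",
]

logger = logging.getLogger(__name__)


def gather_synonyms(hset: HierarchySet, mode: str = "counts") -> pd.DataFrame:
    """Taxonomic synonyms per provider page, counted or listed.

    Coverage varies by provider — a provider may report no synonyms at all
    for a taxon that another provider has several for.
    """
    if mode not in ("counts", "detail"):
        raise ContractError(f"mode must be 'counts' or 'detail', got {mode!r}")
    if mode == "counts":
        rows = [(p.taxon.name, p.entry_id, len(p.synonyms)) for p in hset]
        return pd.DataFrame(rows, columns=["taxon_name", "entry_id", "n_synonyms"])
    rows = [
        (p.taxon.name, p.entry_id, s.name, s.relationship)
        for p in hset for s in p.synonyms
    ]
    return pd.DataFrame(rows, columns=["taxon_name", "entry_id", "synonym", "relationship"])


def taxon_parents(page: HierarchyPage) -> pd.DataFrame:
    """Ancestors of the taxon, most-inclusive first; a root taxon yields an
    empty table."""
    rows = [(a.rank, a.name, a.entry_id) for a in page.ancestors]
    return pd.DataFrame(rows, columns=["rank", "name", "entry_id"])


def taxon_children(page: HierarchyPage) -> pd.DataFrame:
    """Immediate children in provider order; a leaf yields an empty table."""
    rows = [(c.rank, c.name, c.entry_id) for c in page.children]
    return pd.DataFrame(rows, columns=["rank", "name", "entry_id"])


def match_taxa_to_eol_id(names: list[str], transport: Transport, *,
                         exact: bool = False) -> pd.DataFrame:
    """Resolve taxon names to EOL page ids.

    Unresolved names become rows with missing matched-name/id fields —
    queries are never dropped or reordered.
    """
    if not names:
        raise ContractError("names must be non-empty")
    resolved, failures = resolve_names(list(names), transport, exact=exact)
    if failures:
        logger.warning("unresolved names recorded as NA: %s", sorted(failures))
    rows = []
    for name in names:
        hit = resolved.get(name)
        if hit is None:
            rows.append((name, pd.NA, pd.NA))
        else:
            rows.append((name, hit.matched_name, hit.page_id))
    return pd.DataFrame(rows, columns=["query_name", "matched_name", "eol_page_id"])


def _require_unique(keys: list[str], context: str) -> None:
    seen, dups = set(), []
    for k in keys:
        if k in seen:
            dups.append(k)
        seen.add(k)
    if dups:
        raise AmbiguityError(sorted(set(dups)), context)


def match_hier_page_to_eol_data(hset: HierarchySet,
                                eol_table: pd.DataFrame) -> pd.DataFrame:
    """Outer-join provider pages onto an EOL result table by normalized name.

    Every ``eol_table`` row comes back (in order) augmented with
    ``provider`` and ``entry_id`` (missing when no provider page matches);
    provider taxa absent from the table are appended with missing EOL
    fields.  Duplicate normalized names on either side are an error rather
    than a guess.
    """
    if "taxon_name" not in eol_table.columns:
        raise ContractError("eol_table needs a taxon_name column")

    eol_keys = [normalize_name(str(n)) for n in eol_table["taxon_name"]]
    hier_pages = list(hset)
    hier_keys = [normalize_name(p.taxon.name) for p in hier_pages]
    _require_unique(eol_keys, "EOL table taxon names")
    _require_unique(hier_keys, f"{hset.provider} taxon names")
    by_key = dict(zip(hier_keys, hier_pages))

    out = eol_table.copy().reset_index(drop=True)
    out["provider"] = [hset.provider if k in by_key else pd.NA for k in eol_keys]
    out["entry_id"] = [by_key[k].entry_id if k in by_key else pd.NA for k in eol_keys]

    matched = set(eol_keys)
    extra_rows = []
    for key, page in zip(hier_keys, hier_pages):
        if key not in matched:
            row = {c: pd.NA for c in out.columns}
            row["taxon_name"] = page.taxon.name
            row["provider"] = hset.provider
            row["entry_id"] = page.entry_id
            extra_rows.append(row)
    if extra_rows:
        extra = pd.DataFrame(extra_rows, columns=out.columns, dtype=object)
        # object dtype on both sides: appended rows are mostly NA and must
        # not trigger dtype inference churn
        out = pd.concat([out.astype(object), extra], ignore_index=True)
    return out


def vernacular_synonym_report(pages: PageSet, hset: HierarchySet,
                              language: str = "fr", *,
                              empty_token: str | None = None) -> pd.DataFrame:
    """Per-species digest of vernacular names in one language plus the
    provider's taxonomic synonyms (the classroom-handout style report).

    One row per page, in page order; name lists are comma-joined.  With
    ``empty_token`` (e.g. ``"None"``) empty cells render as that token
    instead of an empty string.
    """
    by_key = {normalize_name(p.taxon.name): p for p in hset}
    rows = []
    for page in pages:
        names = [cn.name for cn in page.common_names if cn.language == language]
        hpage = by_key.get(normalize_name(page.scientific_name))
        syns = [s.name for s in hpage.synonyms] if hpage is not None else []
        rows.append((
            page.scientific_name,
            ", ".join(names) or (empty_token or ""),
            ", ".join(syns) or (empty_token or ""),
        ))
    return pd.DataFrame(rows, columns=["taxon_name", f"common_names_{language}", "synonyms"])
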