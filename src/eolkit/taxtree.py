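"""Taxonomic dendrograms from overlapping provider classification pages.

The pipeline is: a :class:`HierarchySet` → :func:`make_tree_data` (a taxon ×
rank matrix with explicit missing cells) → :func:`make_hierarchy_tree` (a
rooted labeled tree by prefix-merging root-to-tip paths) → Newick export and
edge labeling.

Trees can only be built from a complete matrix, so the caller must choose a
missing-rank policy: drop the incomplete taxa (``drop_taxa``), drop the
incomplete ranks (``drop_ranks``, e.g. a genus-level tree when species are
patchy), or refuse (``error``).  There is deliberately no default.

Conventions: one unit of branch length per rank step (collapsed monotypic
chains sum their steps, preserving root-to-tip rank distance); siblings are
ordered alphabetically so output is deterministic; clades with the same name
under different parents (cross-kingdom homonyms) stay distinct nodes because
merging is keyed on the full path, never the bare name.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .api_client import HierarchySet, normalize_name
from .errors import (
    AmbiguityError,
    ConsistencyError,
    ContractError,
    MissingDataError,
    ParseError,
    RankOrderError,
)

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("drop_taxa", "drop_ranks", "error")
DUPLICATE_LABEL_POLICIES = ("recent", "oldest", "all")


# ---------------------------------------------------------------------------
# TreeData


@dataclass
class TreeData:
    """Taxon × rank matrix: rows are terminal taxa, columns are ranks in a
    topological order consistent with every source page; cells hold clade
    names, with None marking a rank the page lacks."""

    rank_order: list[str]
    terminal_names: list[str]
    matrix: pd.DataFrame  # index = terminal_names, columns = rank_order, None for missing

    def missing_cells(self) -> list[tuple[str, str]]:
        """(taxon, rank) pairs with no clade name, row-major order."""
        return [
            (taxon, rank)
            for taxon in self.terminal_names
            for rank in self.rank_order
            if self.matrix.at[taxon, rank] is None
        ]

    def clade_names(self) -> set[str]:
        return {v for v in self.matrix.values.ravel() if v is not None}

    def to_tsv(self, path: str | Path) -> None:
        out = self.matrix.fillna("NA")
        out.index.name = "taxon"
        out.to_csv(path, sep="\t", encoding="utf-8")


def _synthetic_rank(depth: int) -> str:
    # position-based slot so unranked levels (common in NCBI lineages)
    # survive into the matrix instead of being dropped
    return f"clade_depth_{depth}"


def _page_path(page) -> list[tuple[str, str]]:
    """(rank, clade name) pairs root→tip, with synthetic slots for unranked
    levels."""
    entries = list(page.ancestors) + [page.taxon]
    return [
        (rn.rank if rn.rank is not None else _synthetic_rank(depth), rn.name)
        for depth, rn in enumerate(entries)
    ]


def _toposort_ranks(paths: list[list[tuple[str, str]]]) -> list[str]:
    """Order ranks consistently with every page's root→tip order (stable
    Kahn, first-seen tie-break); contradictory orders raise."""
    order_seen: list[str] = []
    successors: dict[str, set[str]] = {}
    indegree: dict[str, int] = {}
    for path in paths:
        ranks = [r for r, _ in path]
        for r in ranks:
            if r not in indegree:
                indegree[r] = 0
                successors[r] = set()
                order_seen.append(r)
        for a, b in zip(ranks, ranks[1:]):
            if a == b:
                raise RankOrderError([a])
            if b not in successors[a]:
                successors[a].add(b)
                indegree[b] += 1

    result = []
    ready = [r for r in order_seen if indegree[r] == 0]
    while ready:
        rank = ready.pop(0)
        result.append(rank)
        newly = []
        for nxt in successors[rank]:
            indegree[nxt] -= 1
            if indegree[nxt] == 0:
                newly.append(nxt)
        ready.extend(sorted(newly, key=order_seen.index))
        ready.sort(key=order_seen.index)
    if len(result) != len(order_seen):
        raise RankOrderError([r for r in order_seen if r not in result])
    return result


def make_tree_data(hset: HierarchySet) -> TreeData:
    """Assemble the taxon × rank matrix from a set of provider pages.

    Each page contributes one row (its taxon) whose cells are the clade
    names along its ancestor path; ranks the page lacks stay missing, which
    is exactly what the matrix is for — showing where classification data
    have gaps before a tree is attempted.
    """
    pages = list(hset)
    if not pages:
        raise ContractError("hierarchy set is empty")
    terminals = [p.taxon.name for p in pages]
    if len(terminals) != len(set(terminals)):
        dups = sorted({t for t in terminals if terminals.count(t) > 1})
        raise AmbiguityError(dups, "terminal taxa")

    paths = [_page_path(p) for p in pages]
    rank_order = _toposort_ranks(paths)

    cells = {t: dict.fromkeys(rank_order) for t in terminals}
    for terminal, path in zip(terminals, paths):
        for rank, name in path:
            cells[terminal][rank] = name
    # build from nested lists so absent cells stay literal None, not NaN
    matrix = pd.DataFrame(
        [[cells[t][r] for r in rank_order] for t in terminals],
        index=terminals, columns=rank_order, dtype=object,
    )
    return TreeData(rank_order=rank_order, terminal_names=terminals, matrix=matrix)


# ---------------------------------------------------------------------------
# TaxonTree


@dataclass
class TreeNode:
    """A node of a taxonomic dendrogram.

    ``collapsed_labels`` records the clade names of monotypic levels that
    were collapsed onto the edge above this node, most-inclusive first
    (they become edge-label candidates).  ``branch_length`` is the number of
    rank steps the edge spans; the root has none.
    """

    label: str
    rank: str | None = None
    branch_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    collapsed_labels: list[str] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __eq__(self, other) -> bool:
        if not isinstance(other, TreeNode):
            return NotImplemented
        return (
            self.label == other.label
            and self.branch_length == other.branch_length
            and self.children == other.children
        )

    def __hash__(self):
        return id(self)


@dataclass
class TaxonTree:
    """Rooted labeled dendrogram with unique tips and no unary internal
    chains (those are collapsed, their labels kept as edge candidates)."""

    root: TreeNode

    def tips(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if node.is_tip:
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, TaxonTree):
            return NotImplemented
        return self.root == other.root


def _apply_policy(data: TreeData, policy: str) -> tuple[list[str], list[str]]:
    """Resolve the missing-rank policy to (retained taxa, retained ranks)."""
    if policy not in MISSING_POLICIES:
        raise ContractError(
            f"missing_rank_policy must be one of {MISSING_POLICIES}, got {policy!r}"
        )
    missing = data.missing_cells()
    if policy == "error":
        if missing:
            raise MissingDataError(missing)
        return list(data.terminal_names), list(data.rank_order)
    if policy == "drop_taxa":
        bad = {taxon for taxon, _ in missing}
        return [t for t in data.terminal_names if t not in bad], list(data.rank_order)
    bad_ranks = {rank for _, rank in missing}
    return list(data.terminal_names), [r for r in data.rank_order if r not in bad_ranks]


def make_hierarchy_tree(data: TreeData, missing_rank_policy: str) -> TaxonTree:
    """Prefix-merge the root-to-tip classification paths into a dendrogram.

    Taxa sharing identical clade names through rank *r* share one node at
    depth ≤ *r* (keyed on the whole path, so homonyms under different
    parents never fuse).  Monotypic chains are collapsed with their labels
    retained; when the top ranks disagree a synthetic root labeled "root"
    joins the kingdoms.  Rows whose retained-rank paths coincide (e.g. two
    congeners after the species rank is dropped) merge into one terminal.
    """
    taxa, ranks = _apply_policy(data, missing_rank_policy)
    if not taxa:
        raise MissingDataError(data.missing_cells(),
                               "no taxon survives the missing-rank policy")
    if not ranks:
        raise MissingDataError(data.missing_cells(),
                               "no rank survives the missing-rank policy")

    seen_paths: dict[tuple[str, ...], str] = {}
    paths: list[list[str]] = []
    for taxon in taxa:
        path = [data.matrix.at[taxon, r] for r in ranks]
        if any(cell is None for cell in path):  # policy guarantees completeness
            raise MissingDataError(
                [(taxon, r) for r, cell in zip(ranks, path) if cell is None]
            )
        key = tuple(path)
        if key in seen_paths:
            warnings.warn(
                f"{taxon!r} and {seen_paths[key]!r} share the retained-rank path "
                f"{key[-1]!r}; merging into one terminal"
            )
            continue
        seen_paths[key] = taxon
        paths.append(path)

    root = TreeNode(label="root", rank=None)
    trie: dict[tuple[str, ...], TreeNode] = {(): root}
    for path in paths:
        for depth in range(len(path)):
            prefix = tuple(path[: depth + 1])
            if prefix not in trie:
                node = TreeNode(label=path[depth], rank=ranks[depth], branch_length=1.0)
                trie[prefix[:-1]].children.append(node)
                trie[prefix] = node

    # descend past the shared prefix: a unary chain at the top has no edge,
    # so its more-inclusive names sit on the root as label candidates
    synthetic_root = root
    while len(root.children) == 1:
        child = root.children[0]
        if root is not synthetic_root:
            child.collapsed_labels = (
                root.collapsed_labels + [root.label] + child.collapsed_labels
            )
        child.branch_length = None
        root = child

    _collapse_unary(root)
    _sort_siblings(root)
    return TaxonTree(root=root)


def _collapse_unary(node: TreeNode) -> None:
    new_children = []
    for child in node.children:
        while len(child.children) == 1:
            only = child.children[0]
            only.collapsed_labels = (
                child.collapsed_labels + [child.label] + only.collapsed_labels
            )
            only.branch_length = (only.branch_length or 0.0) + (child.branch_length or 0.0)
            child = only
        _collapse_unary(child)
        new_children.append(child)
    node.children = new_children


def _sort_siblings(node: TreeNode) -> None:
    node.children.sort(key=lambda c: c.label)
    for child in node.children:
        _sort_siblings(child)


# ---------------------------------------------------------------------------
# Newick


_NEWICK_SAFE = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-")


def _quote_label(label: str) -> str:
    if label and set(label) <= _NEWICK_SAFE:
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: TaxonTree, *, branch_lengths: bool = True) -> str:
    """Serialize deterministically: alphabetical sibling order is already in
    the tree; internal labels are written, lengths optionally."""

    def render(node: TreeNode) -> str:
        if node.is_tip:
            body = _quote_label(node.label)
        else:
            inner = ",".join(render(c) for c in node.children)
            body = f"({inner}){_quote_label(node.label)}"
        if branch_lengths and node.branch_length is not None:
            body += f":{node.branch_length:g}"
        return body

    return render(tree.root) + ";"


def parse_newick(text: str) -> TaxonTree:
    """Parse Newick text into a :class:`TaxonTree` (inverse of
    :func:`write_newick` on its image).  Collapsed-label bookkeeping is not
    representable in Newick and comes back empty."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"invalid Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label or ""
        node = TreeNode(label=label, branch_length=dnode.edge.length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return TaxonTree(root=convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# edge labels


@dataclass
class EdgeLabelMap:
    """Labels for tree edges, keyed by the child node of each edge."""

    labels: dict[TreeNode, str | list[str]]

    def items(self):
        return self.labels.items()

    def __len__(self):
        return len(self.labels)

    def by_child_label(self) -> dict[str, str | list[str]]:
        return {node.label: lab for node, lab in self.labels.items()}

    def total_label_count(self) -> int:
        return sum(len(v) if isinstance(v, list) else 1 for v in self.labels.values())


def make_edge_labels(data: TreeData, tree: TaxonTree,
                     duplicate_policy: str) -> EdgeLabelMap:
    """Assign clade names to the edges above their nodes.

    A collapsed monotypic chain leaves one edge with several candidate
    names, ordered most-inclusive first; ``recent`` keeps the
    least-inclusive, ``oldest`` the most-inclusive, ``all`` the whole list.
    The root has no edge, so names collapsed above the root are not mapped.
    """
    if duplicate_policy not in DUPLICATE_LABEL_POLICIES:
        raise ContractError(
            f"duplicate_policy must be one of {DUPLICATE_LABEL_POLICIES}, "
            f"got {duplicate_policy!r}"
        )
    known = data.clade_names()
    for node in tree.nodes():
        for label in [node.label] + node.collapsed_labels:
            if label != "root" and label not in known:
                raise ConsistencyError(
                    f"tree clade {label!r} does not occur in the tree data"
                )

    labels: dict[TreeNode, str | list[str]] = {}
    for node in tree.nodes():
        if node is tree.root:
            continue
        candidates = node.collapsed_labels + [node.label]
        if duplicate_policy == "recent":
            labels[node] = candidates[-1]
        elif duplicate_policy == "oldest":
            labels[node] = candidates[0]
        else:
            labels[node] = list(candidates)
    return EdgeLabelMap(labels=labels)


# ---------------------------------------------------------------------------
# tip matching


def match_data_to_tree_tips(tree: TaxonTree, table: pd.DataFrame) -> pd.DataFrame:
    """Reorder a per-taxon table to the tree's tip order (for plotting data
    against the dendrogram).

    Tips absent from the table get all-missing rows; table rows matching no
    tip are dropped with a warning; duplicate rows for one tip are an
    error.  The result always has exactly one row per tip, so applying the
    operation twice is the same as applying it once.
    """
    if "taxon_name" not in table.columns:
        raise ContractError("table needs a taxon_name column")
    tip_order = tree.tip_labels()
    tip_keys = {normalize_name(t): t for t in tip_order}

    by_key: dict[str, int] = {}
    dropped = []
    for idx, name in enumerate(table["taxon_name"]):
        key = normalize_name(str(name))
        if key not in tip_keys:
            dropped.append(name)
            continue
        if key in by_key:
            raise AmbiguityError([name], "rows matching one tip")
        by_key[key] = idx

    if dropped:
        warnings.warn(f"rows matching no tree tip were dropped: {dropped}")

    rows = []
    for tip in tip_order:
        key = normalize_name(tip)
        if key in by_key:
            rows.append(table.iloc[by_key[key]])
        else:
            row = pd.Series({c: pd.NA for c in table.columns})
            row["taxon_name"] = tip
            rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)
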