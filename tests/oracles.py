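"""Independent brute-force oracles used to check tree construction.

The oracle merges root-to-tip classification paths one pair at a time into a
nested-dict trie and canonicalizes it (collapsing monotypic chains into label
chains, sorting siblings), sharing no code with the package's prefix-merge
builder.
"""

from __future__ import annotations


def merge_paths(paths: list[list[str]]) -> dict:
    """Insert each path into a nested dict trie, one at a time."""
    root: dict = {}
    for path in paths:
        cursor = root
        for name in path:
            cursor = cursor.setdefault(name, {})
    return root


def _canon_subtree(name: str, subtree: dict) -> tuple:
    chain = [name]
    while len(subtree) == 1:
        (nxt, sub), = subtree.items()
        chain.append(nxt)
        subtree = sub
    children = tuple(sorted(_canon_subtree(n, s) for n, s in subtree.items()))
    return (tuple(chain), float(len(chain)), children)


def oracle_canonical(paths: list[list[str]]) -> tuple:
    """Canonical (label-chain, branch-length, children) form of the merged
    tree: monotypic chains collapsed, siblings sorted, root length None.

    A shared top prefix becomes the root's label chain; fully disjoint top
    ranks hang under a synthetic root labeled "root".
    """
    trie = merge_paths(paths)
    if len(trie) == 1:
        chain = []
        subtree = trie
        while len(subtree) == 1:
            (name, sub), = subtree.items()
            chain.append(name)
            subtree = sub
        children = tuple(sorted(_canon_subtree(n, s) for n, s in subtree.items()))
        return (tuple(chain), None, children)
    children = tuple(sorted(_canon_subtree(n, s) for n, s in trie.items()))
    return (("root",), None, children)


def tree_canonical(tree) -> tuple:
    """The same canonical form computed from a built TaxonTree."""

    def canon(node) -> tuple:
        chain = tuple(node.collapsed_labels + [node.label])
        children = tuple(sorted(canon(c) for c in node.children))
        return (chain, node.branch_length, children)

    return canon(tree.root)
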