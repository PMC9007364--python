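"""Rooted phylogenetic tree utilities shared by the selection and gain stages.

Trees are :class:`dendropy.Tree` objects throughout; this module pins down the
conventions the rest of the package relies on:

* trees are rooted; every node except the seed (root) node has a branch length
  strictly greater than zero;
* edges are addressed by a deterministic integer index assigned in preorder
  (root child edges first), stable across newick round-trips because newick
  serialization preserves child order;
* newick output uses 10-significant-digit branch lengths so that generated
  trees round-trip losslessly at that precision.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Set

import dendropy

__all__ = [
    "read_newick",
    "parse_newick",
    "write_newick",
    "tree_to_newick",
    "edge_index",
    "leaf_labels",
    "total_length",
    "clone_tree",
]


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string into a rooted tree."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        rooting="force-rooted",
    )
    return tree


def read_newick(path: str) -> dendropy.Tree:
    """Read a rooted tree from a newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialize with fixed precision so equal trees give equal bytes."""
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    return s.strip() + "\n"


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree))


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep-copy a tree via newick round-trip (fresh taxon namespace).

    Preorder edge indices are preserved, which is what lets a grafted copy be
    edited without touching the base tree.
    """
    return parse_newick(tree_to_newick(tree))


def edge_index(tree: dendropy.Tree) -> Dict[int, dendropy.Edge]:
    """Map deterministic integer ids to edges (preorder, root edge excluded)."""
    idx: Dict[int, dendropy.Edge] = {}
    i = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        idx[i] = node.edge
        i += 1
    return idx


def leaf_labels(tree: dendropy.Tree) -> List[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def leaves_below(tree: dendropy.Tree) -> Dict[int, Set[str]]:
    """For each indexed edge, the set of leaf labels in the subtree below it."""
    below: Dict[dendropy.Node, Set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {node.taxon.label}
        else:
            s: Set[str] = set()
            for child in node.child_nodes():
                s |= below[child]
            below[node] = s
    return {i: below[e.head_node] for i, e in edge_index(tree).items()}


def total_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (root edge excluded)."""
    return sum(
        node.edge.length or 0.0
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node
    )


def validate_tree(tree: dendropy.Tree) -> None:
    """Check the package's tree invariants; raise ValueError on violation."""
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValueError("leaf labels are not unique")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None or node.edge.length <= 0:
            raise ValueError("all branch lengths must be > 0")
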