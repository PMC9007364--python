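"""Grafting placed genomes onto a reference tree and quantifying the gain.

A placement assigns a query genome (SAG) to an edge of a fixed reference
phylogeny: the edge is split at a position along its length and a pendant
branch carrying the new tip is attached there. Splitting conserves the base
tree's branch length, so the total length of the grafted tree exceeds the
base by exactly the sum of pendant lengths.

Phylogenetic gain is reported per clade of the base tree: for each internal
node, the percentage increase of the branch length inside its subtree (stem
edge excluded) caused by the pendants attached within it. Genome-level
novelty against a reference collection is decided from a pairwise average
nucleotide identity (ANI) table: a genome with no hit strictly above the
threshold (default 97%) is novel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from . import trees

__all__ = [
    "Placement",
    "GraftResult",
    "graft",
    "gain_table",
    "novelty_by_identity",
    "placements_from_frame",
]

ANI_THRESHOLD = 0.97


@dataclass(frozen=True)
class Placement:
    sag_id: str
    edge_ref: int  # preorder edge index in the base tree
    distal_position: float = 0.5  # fraction from the proximal (parent) end
    pendant_length: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.distal_position <= 1.0:
            raise ValueError("distal_position must be in [0, 1]")
        if self.pendant_length < 0:
            raise ValueError("pendant_length must be >= 0")


@dataclass
class GraftResult:
    tree: dendropy.Tree
    placements: Tuple[Placement, ...]
    base_newick: str


def placements_from_frame(df: pd.DataFrame) -> List[Placement]:
    """Build placements from a (sag_id, edge_ref, distal_position,
    pendant_length) table; distal_position defaults to 0.5 when absent."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Placement(
                sag_id=str(row.sag_id),
                edge_ref=int(row.edge_ref),
                distal_position=float(getattr(row, "distal_position", 0.5)),
                pendant_length=float(row.pendant_length),
            )
        )
    return out


def graft(tree: dendropy.Tree, placements: Sequence[Placement]) -> GraftResult:
    """Attach every placement as a pendant tip; the base tree is untouched.

    Multiple placements on one edge are inserted proximal-to-distal; the edge
    is partitioned into segments whose lengths sum to the original length.
    """
    ids = [p.sag_id for p in placements]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sag_id in placements")
    work = trees.clone_tree(tree)
    idx = trees.edge_index(work)
    n_edges = len(idx)
    for p in placements:
        if not 0 <= p.edge_ref < n_edges:
            raise ValueError(f"invalid edge_ref {p.edge_ref}")
    by_edge: Dict[int, List[Placement]] = {}
    for p in placements:
        by_edge.setdefault(p.edge_ref, []).append(p)
    taxa = work.taxon_namespace
    for eref in sorted(by_edge):
        edge = idx[eref]
        child = edge.head_node
        parent = edge.tail_node
        total = float(edge.length)
        # insert from the distal end so earlier split points stay valid
        for p in sorted(
            by_edge[eref], key=lambda q: (-q.distal_position, q.sag_id)
        ):
            upper = total * p.distal_position  # parent-side remainder
            current = float(child.edge.length)
            mid = dendropy.Node()
            parent.remove_child(child)
            parent.add_child(mid)
            mid.add_child(child)
            child.edge.length = current - upper
            mid.edge.length = upper
            tip = dendropy.Node()
            tip.taxon = taxa.new_taxon(p.sag_id)
            tip.edge.length = p.pendant_length
            mid.add_child(tip)
            child = mid
    return GraftResult(work, tuple(placements), trees.tree_to_newick(tree))


def _subtree_edge_refs(base: dendropy.Tree) -> Dict[int, List[int]]:
    """For each base node id (preorder, including root=-1) the edge indices
    inside its subtree (stem excluded)."""
    node_ids: Dict[int, dendropy.Node] = {}
    node_of_edge: Dict[dendropy.Node, int] = {}
    i = 0
    for node in base.preorder_node_iter():
        if node is base.seed_node:
            node_ids[-1] = node
            continue
        node_ids[i] = node
        node_of_edge[node] = i
        i += 1
    refs: Dict[int, List[int]] = {}
    for nid, node in node_ids.items():
        acc: List[int] = []
        stack = list(node.child_nodes())
        while stack:
            cur = stack.pop()
            acc.append(node_of_edge[cur])
            stack.extend(cur.child_nodes())
        refs[nid] = acc
    return refs


def gain_table(base: dendropy.Tree, grafted: GraftResult) -> pd.DataFrame:
    """Per-clade phylogenetic gain of the grafted tips.

    One row per internal node of the base tree (root reported as node_id -1):
    n_placed_below, base_length (subtree branch length, stem excluded),
    added_length (sum of pendant lengths placed inside), and gain_percent =
    100 * added / base. A placement on edge e lies inside every clade whose
    subtree contains e.
    """
    if grafted.base_newick != trees.tree_to_newick(base):
        raise ValueError("grafted tree was not derived from this base tree")
    idx = trees.edge_index(base)
    lengths = {i: float(e.length) for i, e in idx.items()}
    pend: Dict[int, float] = {}
    count: Dict[int, int] = {}
    for p in grafted.placements:
        pend[p.edge_ref] = pend.get(p.edge_ref, 0.0) + p.pendant_length
        count[p.edge_ref] = count.get(p.edge_ref, 0) + 1
    internal = []
    i = 0
    for node in base.preorder_node_iter():
        if node is base.seed_node:
            internal.append(-1)
            continue
        if not node.is_leaf():
            internal.append(i)
        i += 1
    refs = _subtree_edge_refs(base)
    rows = []
    for nid in internal:
        edge_set = refs[nid]
        base_len = sum(lengths[e] for e in edge_set)
        added = sum(pend.get(e, 0.0) for e in edge_set)
        n_below = sum(count.get(e, 0) for e in edge_set)
        rows.append(
            {
                "node_id": nid,
                "n_placed_below": n_below,
                "base_length": base_len,
                "added_length": added,
                "gain_percent": (100.0 * added / base_len) if base_len > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def novelty_by_identity(
    ani_table: pd.DataFrame,
    threshold: float = ANI_THRESHOLD,
    sag_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Novel = no ANI hit strictly above ``threshold``.

    ``ani_table`` has columns (sag_id, reference_id, identity) with identity
    as a fraction in [0, 1]. Genomes listed in ``sag_ids`` but absent from
    the table are novel by definition.
    """
    required = {"sag_id", "reference_id", "identity"}
    if not required.issubset(ani_table.columns):
        raise ValueError(f"ANI table must have columns {sorted(required)}")
    ident = ani_table["identity"].to_numpy(float)
    if ident.size and (np.nanmin(ident) < 0 or np.nanmax(ident) > 1):
        raise ValueError("identity values must be in [0, 1]")
    rows = []
    seen = set()
    if len(ani_table):
        grouped = ani_table.sort_values(
            ["sag_id", "identity"], ascending=[True, False]
        ).groupby("sag_id", sort=True)
        for sag, grp in grouped:
            best = grp.iloc[0]
            seen.add(str(sag))
            rows.append(
                {
                    "sag_id": str(sag),
                    "best_reference": str(best["reference_id"]),
                    "best_identity": float(best["identity"]),
                    "novel": not bool(best["identity"] > threshold),
                }
            )
    for sag in sag_ids or []:
        if str(sag) not in seen:
            rows.append(
                {
                    "sag_id": str(sag),
                    "best_reference": "",
                    "best_identity": np.nan,
                    "novel": True,
                }
            )
    return pd.DataFrame(
        rows, columns=["sag_id", "best_reference", "best_identity", "novel"]
    ).sort_values("sag_id", ignore_index=True)
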