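"""Gene-catalog novelty labeling and annotation-category enrichment.

Query genes are compared against a non-redundant reference gene catalog by
percent nucleotide identity; a gene with no catalog match strictly above the
threshold (default 95%) is novel. The identity engine is a shared-k-mer
prefilter (word size 8, both strands) followed by a banded global alignment;
identity is 1 - edit_distance / alignment_span, which on equal-length
substitution-only pairs is exactly (matching positions) / length.

Greedy longest-first clustering with the same engine dereplicates gene sets
the way CD-HIT-EST does at -c 0.95 -n 8 -r 1 (both strands): sequences sorted
by decreasing length join the first cluster whose representative they match
at or above the identity cutoff, else found their own.

Enrichment of functional categories (e.g. COG letters) in the novel set is
tested by permuting novelty labels over genes, preserving the total novel
count and each gene's category multiset; two-sided p-values use the
+1-corrected permutation rank, adjusted across categories by
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .compare_stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "NoveltyLabel",
    "EnrichmentRow",
    "sequence_identity",
    "dereplicate",
    "label_novelty",
    "overlap_counts",
    "enrichment_test",
]

NOVELTY_THRESHOLD = 0.95
WORD_SIZE = 8
MIN_GENE_LENGTH = 60

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    sequence: str
    category_labels: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_GENE_LENGTH:
            raise ValueError(
                f"gene {self.gene_id}: sequence shorter than {MIN_GENE_LENGTH} nt"
            )


@dataclass(frozen=True)
class NoveltyLabel:
    gene_id: str
    best_match_id: Optional[str]
    best_identity: float
    novel: bool


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    observed_novel: int
    expected_novel: float
    p_value: float
    q_value: float
    direction: str  # enriched | depleted


# ---------------------------------------------------------------------------
# identity engine


def _kmers(seq: str, k: int = WORD_SIZE) -> FrozenSet[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def sequence_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Banded global identity between two sequences (best strand).

    The alignment is capped at an edit distance of half the longer length
    (the band); pairs more distant than that report identity 0.
    """
    best = 0.0
    targets = (b, revcomp(b)) if both_strands else (b,)
    span = max(len(a), len(b))
    k = span // 2 + 1
    for t in targets:
        res = edlib.align(a, t, mode="NW", task="distance", k=k)
        d = res["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / span)
    return best


# ---------------------------------------------------------------------------
# clustering


def dereplicate(
    genes: Sequence[GeneRecord],
    identity: float = NOVELTY_THRESHOLD,
    word_size: int = WORD_SIZE,
) -> Dict[str, str]:
    """Greedy longest-first clustering; returns gene_id -> representative id.

    Order rule: length descending, then gene_id ascending — deterministic for
    any input order.
    """
    ordered = sorted(genes, key=lambda g: (-len(g.sequence), g.gene_id))
    reps: List[GeneRecord] = []
    rep_kmers: List[FrozenSet[str]] = []
    assignment: Dict[str, str] = {}
    for gene in ordered:
        fwd = _kmers(gene.sequence, word_size)
        rev = _kmers(revcomp(gene.sequence), word_size)
        placed = False
        for rep, rk in zip(reps, rep_kmers):
            if not (fwd & rk) and not (rev & rk):
                continue
            if sequence_identity(gene.sequence, rep.sequence) >= identity:
                assignment[gene.gene_id] = rep.gene_id
                placed = True
                break
        if not placed:
            reps.append(gene)
            rep_kmers.append(_kmers(gene.sequence, word_size))
            assignment[gene.gene_id] = gene.gene_id
    return assignment


# ---------------------------------------------------------------------------
# novelty labeling


def label_novelty(
    queries: Sequence[GeneRecord],
    catalog: Sequence[GeneRecord],
    threshold: float = NOVELTY_THRESHOLD,
    word_size: int = WORD_SIZE,
) -> List[NoveltyLabel]:
    """Label each query novel unless some catalog gene matches it at an
    identity strictly above ``threshold``.

    best_identity is the maximum identity over catalog genes sharing at
    least one ``word_size``-mer with the query (either strand); queries with
    no prefilter hit report best_identity 0 and no match id.
    """
    index: Dict[str, List[int]] = {}
    for j, rec in enumerate(catalog):
        for km in _kmers(rec.sequence, word_size):
            index.setdefault(km, []).append(j)
    labels = []
    for q in queries:
        hits = set()
        for km in _kmers(q.sequence, word_size) | _kmers(
            revcomp(q.sequence), word_size
        ):
            hits.update(index.get(km, ()))
        best_id, best = None, 0.0
        for j in sorted(hits):
            ident = sequence_identity(q.sequence, catalog[j].sequence)
            if ident > best:
                best, best_id = ident, catalog[j].gene_id
        labels.append(
            NoveltyLabel(
                gene_id=q.gene_id,
                best_match_id=best_id,
                best_identity=best,
                novel=not best > threshold,
            )
        )
    return labels


def overlap_counts(
    label_sets: Mapping[str, Sequence[NoveltyLabel]]
) -> pd.DataFrame:
    """Shared/unique gene counts versus one or more catalogs (Venn counts).

    Returns one row per catalog (n_known, n_novel, frac_known) plus a
    ``joint`` row: genes known in every catalog and novel against all.
    """
    names = sorted(label_sets)
    if not names:
        raise ValueError("no label sets supplied")
    id_sets = {
        name: [lab.gene_id for lab in label_sets[name]] for name in names
    }
    base = id_sets[names[0]]
    for name in names[1:]:
        if sorted(id_sets[name]) != sorted(base):
            raise ValueError("label sets cover different query genes")
    known = {
        name: {lab.gene_id for lab in label_sets[name] if not lab.novel}
        for name in names
    }
    n_total = len(set(base))
    rows = []
    for name in names:
        k = len(known[name])
        rows.append(
            {
                "catalog": name,
                "n_known": k,
                "n_novel": n_total - k,
                "frac_known": k / n_total if n_total else np.nan,
            }
        )
    joint_known = set.intersection(*known.values()) if names else set()
    joint_novel = set(base) - set.union(*known.values())
    rows.append(
        {
            "catalog": "joint",
            "n_known": len(joint_known),
            "n_novel": len(joint_novel),
            "frac_known": len(joint_known) / n_total if n_total else np.nan,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment


def enrichment_test(
    labels: Sequence[NoveltyLabel],
    genes: Sequence[GeneRecord],
    n_permutations: int = 2000,
    seed: int = 0,
) -> List[EnrichmentRow]:
    """Permutation test for category enrichment/depletion among novel genes.

    The null permutes which genes are novel while keeping the number of novel
    genes and every gene's category multiset fixed. The two-sided p-value is
    the +1-corrected permutation rank of |observed - null mean| within the
    null's absolute deviations; q-values are Benjamini-Hochberg across the
    tested categories.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    novelty = {lab.gene_id: lab.novel for lab in labels}
    recs = [g for g in genes if g.gene_id in novelty]
    if len(recs) != len(novelty):
        missing = set(novelty) - {g.gene_id for g in recs}
        raise ValueError(f"labels without gene records: {sorted(missing)[:5]}")
    categories = sorted({c for g in recs for c in g.category_labels})
    kept = []
    for cat in categories:
        if any(cat in g.category_labels for g in recs):
            kept.append(cat)
        else:  # pragma: no cover - guarded by construction above
            logger.warning("category %s has no annotated genes; omitted", cat)
    if not kept:
        return []
    n_genes = len(recs)
    membership = np.zeros((n_genes, len(kept)), dtype=float)
    cat_pos = {c: j for j, c in enumerate(kept)}
    is_novel = np.zeros(n_genes, dtype=bool)
    for i, g in enumerate(recs):
        is_novel[i] = novelty[g.gene_id]
        for c in g.category_labels:
            membership[i, cat_pos[c]] = 1.0
    observed = is_novel.astype(float) @ membership
    n_novel = int(is_novel.sum())

    rng = np.random.default_rng(seed)
    # each row of perm_flags is one permutation of the novelty vector
    order = np.argsort(rng.random((n_permutations, n_genes)), axis=1)
    perm_flags = (order < n_novel).astype(float)
    null_counts = perm_flags @ membership  # (n_perm, n_cat)
    expected = null_counts.mean(axis=0)

    dev = np.abs(null_counts - expected)
    p = (1 + (dev >= np.abs(observed - expected)).sum(axis=0)) / (
        n_permutations + 1
    )
    q = bh_adjust(list(p))
    rows = []
    for j, cat in enumerate(kept):
        rows.append(
            EnrichmentRow(
                category=cat,
                observed_novel=int(observed[j]),
                expected_novel=float(expected[j]),
                p_value=float(p[j]),
                q_value=float(q[j]),
                direction="enriched" if observed[j] >= expected[j] else "depleted",
            )
        )
    return rows
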