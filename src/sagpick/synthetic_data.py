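"""Synthetic inputs with controlled ground truth for every pipeline stage.

The generator emulates the data a single-cell genomics screen produces:

* a rooted reference phylogeny (random binary topology, i.i.d. exponential
  branch lengths) standing in for a fixed genome tree;
* per-cell whole-genome-amplification fluorescence curves — 4-parameter
  logistic plus Gaussian noise, with a configurable fraction of flat
  (failed-amplification) wells;
* contig sets ("assemblies") drawn from genome-specific 3rd-order Markov
  chains, pure or 50:50 two-genome mixtures emulating co-sorted cells;
* a gene catalog plus query genes mutated to exact target identities (and
  fresh random sequences as true novelties);
* candidate placements of cells onto the reference tree and a paired
  classifier-performance metric table for the comparison stage.

Everything is a pure function of :class:`SimConfig`; the same config yields
byte-identical files, and every generated object has exactly one ground-truth
record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from . import trees

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_tree",
    "make_curves",
    "make_assemblies",
    "make_gene_sets",
    "make_placements",
    "make_metric_table",
    "simulate_all",
    "write_outputs",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

# fixed stream keys so adding a generator never perturbs existing streams
_STREAMS = {
    "tree": 0,
    "curves": 1,
    "assemblies": 2,
    "genes": 3,
    "placements": 4,
    "metrics": 5,
}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults describe a screen of 200 sorted cells against a 100-leaf
    reference tree, 5% fluorescence noise, a 10% amplification failure rate,
    40 kb genomes and a 10% doublet (contamination) rate.
    """

    seed: int = 0
    n_leaves: int = 100
    branch_length_mean: float = 0.1
    n_cells: int = 200
    curve_noise_sd: float = 50.0  # fluorescence units; amplitude is ~1000
    failure_rate: float = 0.1
    genome_length: int = 40_000
    contamination_fraction: float = 0.1
    catalog_size: int = 200
    identity_targets: Tuple[float, ...] = (1.0, 0.97, 0.96, 0.95, 0.90)
    # secondary knobs (fixed study conditions, rarely changed)
    n_source_genomes: int = 12
    genes_per_target: int = 25
    n_novel_genes: int = 25
    gene_length_range: Tuple[int, int] = (600, 1500)
    n_metric_samples: int = 12
    metric_effect: float = 0.3

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        for name in ("failure_rate", "contamination_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for t in self.identity_targets:
            if not 0.5 < t <= 1.0:
                raise ValueError(f"identity targets must be in (0.5, 1], got {t}")
        if self.genome_length < 8_000:
            raise ValueError("genome_length must be >= 8 kb")
        if self.branch_length_mean <= 0:
            raise ValueError("branch_length_mean must be > 0")


@dataclass
class GroundTruth:
    """Per-object truth records, one entry per generated object."""

    true_inflection_times: Dict[str, Optional[float]] = field(default_factory=dict)
    failed_cells: Dict[str, bool] = field(default_factory=dict)
    true_sources: Dict[str, List[str]] = field(default_factory=dict)
    true_identity: Dict[str, float] = field(default_factory=dict)
    novel_genes: Dict[str, bool] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# reference tree


def make_tree(config: SimConfig) -> dendropy.Tree:
    """Random rooted binary tree by sequential leaf attachment.

    Branch lengths are i.i.d. Exponential(branch_length_mean), assigned in
    preorder after the topology is built, so the expected total length of an
    n-leaf tree is (2n-2) * branch_length_mean.
    """
    rng = _rng(config, "tree")
    n = config.n_leaves
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    labels = [f"L{i+1:04d}" for i in range(n)]

    def new_leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label)
        return node

    tree.seed_node.add_child(new_leaf(labels[0]))
    tree.seed_node.add_child(new_leaf(labels[1]))
    nodes: List[dendropy.Node] = list(tree.seed_node.child_nodes())
    for label in labels[2:]:
        # split a uniformly chosen existing edge (edge above `target`)
        target = nodes[int(rng.integers(len(nodes)))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = new_leaf(label)
        mid.add_child(leaf)
        nodes.extend([mid, leaf])
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        node.edge.length = float(rng.exponential(config.branch_length_mean))
        while node.edge.length == 0.0:  # exponential can underflow to 0
            node.edge.length = float(rng.exponential(config.branch_length_mean))
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# amplification curves

CURVE_TIME_GRID = np.arange(0.0, 601.0, 5.0)  # minutes, 121 points


def logistic_curve(
    t: np.ndarray, f0: float, a: float, r: float, tinf: float
) -> np.ndarray:
    """4-parameter logistic: F(t) = F0 + A / (1 + exp(-r (t - tinf)))."""
    return f0 + a / (1.0 + np.exp(-r * (t - tinf)))


def make_curves(
    config: SimConfig, times: Optional[np.ndarray] = None
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Per-cell fluorescence time series in long form.

    Returns a DataFrame (cell_id, time_min, fluorescence) and ground truth
    with the true inflection time of each successful cell (None for the
    failure_rate fraction of flat, noise-only wells).
    """
    rng = _rng(config, "curves")
    t = CURVE_TIME_GRID if times is None else np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    truth = GroundTruth()
    frames = []
    for i in range(config.n_cells):
        cell = f"C{i+1:04d}"
        failed = bool(rng.random() < config.failure_rate)
        f0 = rng.uniform(50.0, 150.0)
        if failed:
            y = np.full_like(t, f0)
            truth.true_inflection_times[cell] = None
        else:
            a = rng.uniform(800.0, 1200.0)
            r = rng.uniform(0.05, 0.2)
            tinf = rng.uniform(100.0, 450.0)
            y = logistic_curve(t, f0, a, r, tinf)
            truth.true_inflection_times[cell] = float(tinf)
        truth.failed_cells[cell] = failed
        if config.curve_noise_sd > 0:
            y = y + rng.normal(0.0, config.curve_noise_sd, size=t.shape)
        frames.append(
            pd.DataFrame({"cell_id": cell, "time_min": t, "fluorescence": y})
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell_id", "time_min", "fluorescence"])
    )
    return df, truth


# ---------------------------------------------------------------------------
# assemblies with genome-specific tetranucleotide composition


def _random_transition_matrix(rng: np.random.Generator) -> np.ndarray:
    """Random 3rd-order Markov chain: 64 contexts x 4 next-base probabilities.

    A small Dirichlet concentration gives strongly skewed rows, i.e. distinct
    tetramer signatures between independently drawn genomes.
    """
    return rng.dirichlet(np.full(4, 0.5), size=64)


def _sample_markov_sequence(
    rng: np.random.Generator, trans: np.ndarray, length: int
) -> str:
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0
    out = np.empty(length, dtype=np.int64)
    u = rng.random(length)
    # seed context uniformly
    ctx = int(rng.integers(64))
    out[0] = ctx >> 4
    out[1] = (ctx >> 2) & 3
    out[2] = ctx & 3
    row = cum[ctx]
    for i in range(3, length):
        ui = u[i]
        b = 0
        if ui >= row[0]:
            b = 1
            if ui >= row[1]:
                b = 2
                if ui >= row[2]:
                    b = 3
        out[i] = b
        ctx = ((ctx << 2) | b) & 63
        row = cum[ctx]
    return "".join(_BASES[out])


def _cut_into_contigs(
    rng: np.random.Generator, seq: str, min_contig: int = 2500
) -> List[str]:
    """Cut a sequence into 3-10 contigs at random breakpoints."""
    n = len(seq)
    max_parts = max(1, min(10, n // min_contig))
    k = int(rng.integers(3, max_parts + 1)) if max_parts >= 3 else max_parts
    if k <= 1:
        return [seq]
    cuts = np.sort(rng.choice(np.arange(min_contig, n - min_contig + 1), size=k - 1,
                              replace=False)) if n - 2 * min_contig >= k - 1 else []
    pieces, start = [], 0
    for c in list(cuts) + [n]:
        if c - start >= 1:
            pieces.append(seq[start:c])
        start = c
    return pieces


def make_assemblies(config: SimConfig) -> Tuple[Dict[str, List[str]], GroundTruth]:
    """Assemblies as contig lists keyed by assembly id.

    A pool of ``n_source_genomes`` genomes is drawn, each from its own random
    3rd-order Markov chain. Pure assemblies cut contigs from one genome; a
    ``contamination_fraction`` of assemblies interleave contigs from two
    genomes at a 50:50 (+/-10%) length share — the canonical doublet model for
    two co-sorted cells.
    """
    rng = _rng(config, "assemblies")
    n_genomes = max(2, config.n_source_genomes)
    genomes = {}
    for g in range(n_genomes):
        trans = _random_transition_matrix(rng)
        genomes[f"G{g+1:03d}"] = _sample_markov_sequence(
            rng, trans, config.genome_length
        )
    names = sorted(genomes)
    truth = GroundTruth()
    assemblies: Dict[str, List[str]] = {}
    for i in range(config.n_cells):
        aid = f"A{i+1:04d}"
        contaminated = bool(rng.random() < config.contamination_fraction)
        if contaminated:
            g1, g2 = rng.choice(len(names), size=2, replace=False)
            share = 0.5 + rng.uniform(-0.1, 0.1)
            len1 = int(round(share * config.genome_length))
            s1 = genomes[names[g1]][:len1]
            s2 = genomes[names[g2]][: config.genome_length - len1]
            contigs = _cut_into_contigs(rng, s1) + _cut_into_contigs(rng, s2)
            order = rng.permutation(len(contigs))
            contigs = [contigs[j] for j in order]
            truth.true_sources[aid] = [names[g1], names[g2]]
        else:
            g1 = int(rng.integers(len(names)))
            contigs = _cut_into_contigs(rng, genomes[names[g1]])
            truth.true_sources[aid] = [names[g1]]
        assemblies[aid] = contigs
    return assemblies, truth


# ---------------------------------------------------------------------------
# gene sets


def _random_gene(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_to_identity(
    rng: np.random.Generator, seq: str, identity: float
) -> Tuple[str, float]:
    """Substitute exactly round((1-identity)*len) positions to different bases.

    Returns the mutated sequence and the realized identity 1 - k/len.
    """
    n = len(seq)
    k = int(round((1.0 - identity) * n))
    if k == 0:
        return seq, 1.0
    pos = rng.choice(n, size=k, replace=False)
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1").copy()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for p in pos:
        cur = idx[arr[p]]
        arr[p] = _BASES[(cur + 1 + int(rng.integers(3))) % 4]
    return "".join(arr), 1.0 - k / n


def make_gene_sets(
    config: SimConfig,
) -> Tuple[Dict[str, str], Dict[str, str], GroundTruth]:
    """(catalog, queries, truth): queries are catalog mutants or fresh novels.

    For each identity target, ``genes_per_target`` queries are derived from
    random catalog parents by exact-count point substitution; a further
    ``n_novel_genes`` queries are fresh random sequences (true novels).
    """
    rng = _rng(config, "genes")
    lo, hi = config.gene_length_range
    catalog = {
        f"CAT{i+1:05d}": _random_gene(rng, int(rng.integers(lo, hi + 1)))
        for i in range(config.catalog_size)
    }
    cat_ids = sorted(catalog)
    truth = GroundTruth()
    queries: Dict[str, str] = {}
    q = 0
    for target in config.identity_targets:
        for _ in range(config.genes_per_target):
            q += 1
            qid = f"Q{q:05d}"
            parent = cat_ids[int(rng.integers(len(cat_ids)))]
            seq, realized = mutate_to_identity(rng, catalog[parent], target)
            queries[qid] = seq
            truth.true_identity[qid] = realized
            truth.novel_genes[qid] = realized <= 0.95
    for _ in range(config.n_novel_genes):
        q += 1
        qid = f"Q{q:05d}"
        queries[qid] = _random_gene(rng, int(rng.integers(lo, hi + 1)))
        truth.true_identity[qid] = 0.0
        truth.novel_genes[qid] = True
    return catalog, queries, truth


# ---------------------------------------------------------------------------
# placements and classifier metric table


def make_placements(config: SimConfig, tree: dendropy.Tree) -> pd.DataFrame:
    """One candidate placement per cell: (sag_id, edge_ref, distal_position,
    pendant_length), edges chosen uniformly, pendants Exponential(mean/2)."""
    rng = _rng(config, "placements")
    n_edges = len(trees.edge_index(tree))
    rows = []
    for i in range(config.n_cells):
        pendant = float(rng.exponential(config.branch_length_mean / 2.0))
        while pendant == 0.0:
            pendant = float(rng.exponential(config.branch_length_mean / 2.0))
        rows.append(
            {
                "sag_id": f"C{i+1:04d}",
                "edge_ref": int(rng.integers(n_edges)),
                "distal_position": float(rng.uniform(0.05, 0.95)),
                "pendant_length": pendant,
            }
        )
    return pd.DataFrame(rows)


def make_metric_table(config: SimConfig) -> pd.DataFrame:
    """Paired classifier-performance table for the comparison stage.

    Two conditions per metric: a reference database alone and the same
    database augmented with the new genomes; the augmented condition has a
    multiplicative uplift of ``metric_effect`` plus lognormal sample noise.
    """
    rng = _rng(config, "metrics")
    rows = []
    for metric, base in (("kmer_hashes", 50_000.0), ("marker_coverage", 12.0)):
        for i in range(config.n_metric_samples):
            sample = f"S{i+1:03d}"
            level = base * float(rng.lognormal(0.0, 0.4))
            noise = float(rng.lognormal(0.0, 0.05))
            rows.append(
                {
                    "sample_id": sample,
                    "condition": "db_default",
                    "metric_name": metric,
                    "value": level,
                }
            )
            rows.append(
                {
                    "sample_id": sample,
                    "condition": "db_augmented",
                    "metric_name": metric,
                    "value": level * (1.0 + config.metric_effect) * noise,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle + file emission


def simulate_all(config: SimConfig) -> dict:
    """Generate every pipeline input; returns a dict of in-memory objects."""
    tree = make_tree(config)
    curves, curve_truth = make_curves(config)
    assemblies, asm_truth = make_assemblies(config)
    catalog, queries, gene_truth = make_gene_sets(config)
    placements = make_placements(config, tree)
    metrics = make_metric_table(config)
    truth = GroundTruth(
        true_inflection_times=curve_truth.true_inflection_times,
        failed_cells=curve_truth.failed_cells,
        true_sources=asm_truth.true_sources,
        true_identity=gene_truth.true_identity,
        novel_genes=gene_truth.novel_genes,
    )
    return {
        "tree": tree,
        "curves": curves,
        "assemblies": assemblies,
        "catalog": catalog,
        "queries": queries,
        "placements": placements,
        "metrics": metrics,
        "truth": truth,
    }


def _write_fasta(path, records: Dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_outputs(config: SimConfig, outdir: str) -> dict:
    """Write all synthetic inputs under ``outdir``; returns the bundle."""
    import os

    os.makedirs(outdir, exist_ok=True)
    asm_dir = os.path.join(outdir, "assemblies")
    os.makedirs(asm_dir, exist_ok=True)
    bundle = simulate_all(config)
    trees.write_newick(bundle["tree"], os.path.join(outdir, "tree.nwk"))
    bundle["curves"].to_csv(
        os.path.join(outdir, "curves.csv"), index=False, float_format="%.6f"
    )
    for aid in sorted(bundle["assemblies"]):
        contigs = bundle["assemblies"][aid]
        _write_fasta(
            os.path.join(asm_dir, f"{aid}.fasta"),
            {f"{aid}_c{j+1}": s for j, s in enumerate(contigs)},
        )
    _write_fasta(os.path.join(outdir, "catalog.fasta"), bundle["catalog"])
    _write_fasta(os.path.join(outdir, "genes.fasta"), bundle["queries"])
    bundle["placements"].to_csv(
        os.path.join(outdir, "placements.tsv"), sep="\t", index=False,
        float_format="%.10g",
    )
    bundle["metrics"].to_csv(
        os.path.join(outdir, "metrics.tsv"), sep="\t", index=False,
        float_format="%.6f",
    )
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        fh.write(bundle["truth"].to_json())
    return bundle
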