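"""End-to-end orchestration: simulate -> qc -> cost -> select -> gain ->
novelty -> compare -> report.

Stages are isolated through on-disk artifacts (TSV/CSV/FASTA/newick/JSON) so
each is independently runnable and the whole run is a pure function of
(config, seed): identical configs give byte-identical data outputs. A run
manifest records the config hash, per-stage row counts and output checksums
(timestamps excluded from the determinism contract).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import (
    amplification_cost,
    assembly_qc,
    catalog_novelty,
    compare_stats,
    pd_select,
    phylo_gain,
    synthetic_data,
    trees,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report", "load_config"]

STAGES = ("simulate", "qc", "cost", "select", "gain", "novelty", "compare")


@dataclass(frozen=True)
class RunConfig:
    """All tunables in one place; defaults are the pipeline's canonical
    thresholds (assembly floor 20 kb, trim 100 bp / contig floor 2 kb, gene
    identity 0.95, ANI 0.97, selection cap 150, prevalence floor 5 hashes,
    display alpha 0.1)."""

    seed: int = 0
    outdir: str = "sagpick_run"
    stages: tuple = STAGES
    # simulate
    n_leaves: int = 100
    n_cells: int = 200
    # qc
    min_assembly_length: int = assembly_qc.MIN_ASSEMBLY_LENGTH
    end_trim: int = assembly_qc.DEFAULT_END_TRIM
    min_contig_length: int = assembly_qc.DEFAULT_MIN_CONTIG
    tetramer_window: int = assembly_qc.DEFAULT_WINDOW
    contamination_threshold: float = assembly_qc.DEFAULT_SCORE_THRESHOLD
    # select
    cap: int = 150
    budget: float = math.inf
    solver: str = "exact"  # exact | greedy
    # novelty
    gene_identity_threshold: float = catalog_novelty.NOVELTY_THRESHOLD
    ani_threshold: float = phylo_gain.ANI_THRESHOLD
    enrichment_permutations: int = 2000
    # compare
    prevalence_min_hashes: int = 5
    alpha: float = compare_stats.ALPHA_DISPLAY

    def sim_config(self) -> synthetic_data.SimConfig:
        return synthetic_data.SimConfig(
            seed=self.seed, n_leaves=self.n_leaves, n_cells=self.n_cells
        )


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    if "budget" in data and data["budget"] in (None, "inf"):
        data["budget"] = math.inf
    return RunConfig(**data)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_rows: Dict[str, int] = field(default_factory=dict)
    checksums: Dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: (repr(v) if isinstance(v, float) else v)
         for k, v in dataclasses.asdict(config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def _validate_stage_order(config: RunConfig) -> None:
    on = set(config.stages)
    unknown = on - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    needs = {
        "qc": {"simulate"},
        "cost": {"simulate"},
        "select": {"simulate", "qc", "cost"},
        "gain": {"simulate", "select"},
        "novelty": {"simulate"},
        "compare": {"simulate"},
    }
    for stage, deps in needs.items():
        if stage in on and not deps.issubset(on):
            raise ValueError(
                f"stage '{stage}' requires stages {sorted(deps - on)} "
                "to be enabled (no precomputed inputs supplied)"
            )


# ---------------------------------------------------------------------------
# stages (each reads/writes under outdir)


def _stage_qc(config: RunConfig, outdir: str) -> pd.DataFrame:
    asm_dir = os.path.join(outdir, "sim", "assemblies")
    rows = []
    for fname in sorted(os.listdir(asm_dir)):
        if not fname.endswith(".fasta"):
            continue
        aid = fname[: -len(".fasta")]
        contigs = _read_fasta_seqs(os.path.join(asm_dir, fname))
        m = assembly_qc.evaluate_assembly(
            contigs,
            min_assembly_length=config.min_assembly_length,
            window=config.tetramer_window,
            score_threshold=config.contamination_threshold,
        )
        rows.append({"assembly_id": aid, **dataclasses.asdict(m)})
    df = pd.DataFrame(rows)
    df["qc_pass"] = df["pass_length_filter"] & ~df["contamination_flag"]
    df.to_csv(
        os.path.join(outdir, "qc.tsv"), sep="\t", index=False,
        float_format="%.6f",
    )
    return df


def _read_fasta_seqs(path: str) -> List[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]


def _stage_cost(config: RunConfig, outdir: str) -> pd.DataFrame:
    curves = pd.read_csv(os.path.join(outdir, "sim", "curves.csv"))
    costs = amplification_cost.costs_from_curves(curves)
    costs.to_csv(
        os.path.join(outdir, "costs.tsv"), sep="\t", index=False,
        float_format="%.6f",
    )
    return costs


def _cell_to_assembly(cell_id: str) -> str:
    return "A" + cell_id[1:]


def _stage_select(config: RunConfig, outdir: str) -> pd.DataFrame:
    tree = trees.read_newick(os.path.join(outdir, "sim", "tree.nwk"))
    placements_df = pd.read_csv(
        os.path.join(outdir, "sim", "placements.tsv"), sep="\t"
    )
    qc = pd.read_csv(os.path.join(outdir, "qc.tsv"), sep="\t")
    costs = pd.read_csv(os.path.join(outdir, "costs.tsv"), sep="\t")
    ok_assemblies = set(qc.loc[qc["qc_pass"], "assembly_id"])
    cost_map = dict(zip(costs["cell_id"], costs["cost"]))
    eligible = placements_df[
        placements_df["sag_id"].map(
            lambda c: _cell_to_assembly(c) in ok_assemblies
            and math.isfinite(cost_map.get(c, math.inf))
        )
    ]
    placements = phylo_gain.placements_from_frame(eligible)
    grafted = phylo_gain.graft(tree, placements)
    candidates = tuple(p.sag_id for p in placements)
    problem = pd_select.SelectionProblem(
        tree=grafted.tree,
        candidates=candidates,
        cost={c: float(cost_map[c]) for c in candidates},
        budget=config.budget,
        cap=config.cap,
        anchored=True,
    )
    solver = pd_select.solve_exact if config.solver == "exact" else pd_select.solve_greedy
    result = solver(problem)
    pd_select.validate_result(problem, result)
    chosen = set(result.chosen)
    sel = eligible.copy()
    sel["chosen"] = sel["sag_id"].isin(chosen)
    sel = sel.sort_values("sag_id", ignore_index=True)
    sel.to_csv(
        os.path.join(outdir, "selection.tsv"), sep="\t", index=False,
        float_format="%.10g",
    )
    with open(os.path.join(outdir, "selection.json"), "w") as fh:
        json.dump(
            {
                "solver": result.solver,
                "pd": result.pd,
                "total_cost": result.total_cost,
                "n_chosen": len(result.chosen),
                "budget": "inf" if math.isinf(config.budget) else config.budget,
                "cap": config.cap,
                "optimal": result.optimal,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return sel


def _stage_gain(config: RunConfig, outdir: str) -> pd.DataFrame:
    tree = trees.read_newick(os.path.join(outdir, "sim", "tree.nwk"))
    sel = pd.read_csv(os.path.join(outdir, "selection.tsv"), sep="\t")
    chosen = sel[sel["chosen"]]
    placements = phylo_gain.placements_from_frame(chosen)
    grafted = phylo_gain.graft(tree, placements)
    gain = phylo_gain.gain_table(tree, grafted)
    gain.to_csv(
        os.path.join(outdir, "gain.tsv"), sep="\t", index=False,
        float_format="%.6f",
    )
    return gain


def _stage_novelty(config: RunConfig, outdir: str) -> pd.DataFrame:
    from Bio import SeqIO

    def load(path):
        return [
            catalog_novelty.GeneRecord(rec.id, str(rec.seq))
            for rec in SeqIO.parse(path, "fasta")
        ]

    catalog = load(os.path.join(outdir, "sim", "catalog.fasta"))
    queries = load(os.path.join(outdir, "sim", "genes.fasta"))
    labels = catalog_novelty.label_novelty(
        queries, catalog, threshold=config.gene_identity_threshold
    )
    df = pd.DataFrame(
        [
            {
                "gene_id": lab.gene_id,
                "best_match_id": lab.best_match_id or "",
                "best_identity": lab.best_identity,
                "novel": lab.novel,
            }
            for lab in labels
        ]
    )
    df.to_csv(
        os.path.join(outdir, "novelty.tsv"), sep="\t", index=False,
        float_format="%.6f",
    )
    # category enrichment over simulated COG-letter annotations
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(101,))
    )
    letters = list("CDEFGHIJKLMNOPQRSTUV")
    annotated = [
        catalog_novelty.GeneRecord(
            q.gene_id,
            q.sequence,
            frozenset(
                rng.choice(letters, size=int(rng.integers(1, 3)), replace=False)
            ),
        )
        for q in queries
    ]
    enrich = catalog_novelty.enrichment_test(
        labels,
        annotated,
        n_permutations=config.enrichment_permutations,
        seed=config.seed,
    )
    pd.DataFrame([dataclasses.asdict(r) for r in enrich]).to_csv(
        os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    return df


def _stage_compare(config: RunConfig, outdir: str) -> pd.DataFrame:
    metrics = pd.read_csv(os.path.join(outdir, "sim", "metrics.tsv"), sep="\t")
    tests = compare_stats.compare_table(metrics, paired=True, alpha=config.alpha)
    tests.to_csv(
        os.path.join(outdir, "tests.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    return tests


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the enabled stages in dependency order under ``config.outdir``."""
    _validate_stage_order(config)
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, started=time.time()
    )
    on = set(config.stages)
    try:
        if "simulate" in on:
            logger.info("stage simulate")
            bundle = synthetic_data.write_outputs(
                config.sim_config(), os.path.join(outdir, "sim")
            )
            manifest.stage_rows["simulate"] = len(bundle["curves"])
        if "qc" in on:
            logger.info("stage qc")
            manifest.stage_rows["qc"] = len(_stage_qc(config, outdir))
        if "cost" in on:
            logger.info("stage cost")
            manifest.stage_rows["cost"] = len(_stage_cost(config, outdir))
        if "select" in on:
            logger.info("stage select")
            manifest.stage_rows["select"] = len(_stage_select(config, outdir))
        if "gain" in on:
            logger.info("stage gain")
            manifest.stage_rows["gain"] = len(_stage_gain(config, outdir))
        if "novelty" in on:
            logger.info("stage novelty")
            manifest.stage_rows["novelty"] = len(_stage_novelty(config, outdir))
        if "compare" in on:
            logger.info("stage compare")
            manifest.stage_rows["compare"] = len(_stage_compare(config, outdir))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    for name in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, name)
        if os.path.isfile(path):
            manifest.checksums[name] = _checksum(path)
    manifest.finished = time.time()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest


def report(outdir: str) -> dict:
    """Aggregate a completed run into one JSON-serializable summary."""
    out: dict = {"gaps": []}

    def maybe(name, fn):
        path = os.path.join(outdir, name)
        if os.path.exists(path):
            fn(path)
        else:
            out["gaps"].append(name)

    def qc_section(path):
        qc = pd.read_csv(path, sep="\t")
        summaries = {}
        for metric in ("n_contigs", "total_length", "longest_contig", "gc_fraction"):
            s = assembly_qc.summarize(qc[metric].dropna())
            summaries[metric] = dataclasses.asdict(s)
        out["qc"] = {
            "n_assemblies": int(len(qc)),
            "n_pass": int(qc["qc_pass"].sum()),
            "five_number_summaries": summaries,
        }

    def sel_section(path):
        with open(path) as fh:
            out["selection"] = json.load(fh)

    def gain_section(path):
        gain = pd.read_csv(path, sep="\t")
        root = gain[gain["node_id"] == -1].iloc[0]
        out["gain"] = {
            "root_added_length": float(root["added_length"]),
            "root_gain_percent": float(root["gain_percent"]),
            "n_placed": int(root["n_placed_below"]),
        }

    def novelty_section(path):
        labels = pd.read_csv(path, sep="\t")
        out["novelty"] = {
            "n_genes": int(len(labels)),
            "novel_fraction": float(labels["novel"].mean()),
        }

    def tests_section(path):
        out["tests"] = pd.read_csv(path, sep="\t").to_dict(orient="records")

    maybe("qc.tsv", qc_section)
    maybe("selection.json", sel_section)
    maybe("gain.tsv", gain_section)
    maybe("novelty.tsv", novelty_section)
    maybe("tests.tsv", tests_section)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out
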