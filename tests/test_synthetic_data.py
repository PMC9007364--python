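"""Generator contracts: determinism, ground-truth bookkeeping, and the
statistical shape of what gets emitted."""

import json

import numpy as np
import pytest

from sagpick import assembly_qc, synthetic_data as sd, trees


class TestMakeTree:
    def test_smallest_tree_has_two_leaves_and_two_pendant_edges(self):
        tree = sd.make_tree(sd.SimConfig(seed=0, n_leaves=2))
        assert sorted(trees.leaf_labels(tree)) == ["L0001", "L0002"]
        assert len(trees.edge_index(tree)) == 2

    def test_same_seed_gives_identical_newick(self):
        cfg = sd.SimConfig(seed=1, n_leaves=10)
        assert trees.tree_to_newick(sd.make_tree(cfg)) == trees.tree_to_newick(
            sd.make_tree(cfg)
        )

    def test_newick_round_trip_preserves_lengths(self):
        tree = sd.make_tree(sd.SimConfig(seed=5, n_leaves=25))
        back = trees.parse_newick(trees.tree_to_newick(tree))
        assert trees.total_length(back) == pytest.approx(
            trees.total_length(tree), rel=1e-9
        )
        trees.validate_tree(back)

    def test_total_length_matches_exponential_expectation(self):
        # 200 replicates of a 50-leaf tree: mean total length should sit
        # within 3 standard errors of (2n-2)*mean under i.i.d. Exp lengths
        n, mean, reps = 50, 0.1, 200
        totals = [
            trees.total_length(
                sd.make_tree(
                    sd.SimConfig(seed=s, n_leaves=n, branch_length_mean=mean)
                )
            )
            for s in range(reps)
        ]
        n_edges = 2 * n - 2
        expected = n_edges * mean
        se = mean * np.sqrt(n_edges) / np.sqrt(reps)
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_rejects_single_leaf(self):
        with pytest.raises(ValueError):
            sd.SimConfig(seed=0, n_leaves=1)


class TestMakeCurves:
    def test_noiseless_curve_steepest_at_true_inflection(self):
        cfg = sd.SimConfig(seed=2, n_cells=1, curve_noise_sd=0.0, failure_rate=0.0)
        df, truth = sd.make_curves(cfg)
        tinf = truth.true_inflection_times["C0001"]
        grp = df.sort_values("time_min")
        slope = np.diff(grp["fluorescence"]) / np.diff(grp["time_min"])
        t_mid = (grp["time_min"].to_numpy()[:-1] + grp["time_min"].to_numpy()[1:]) / 2
        assert abs(t_mid[np.argmax(slope)] - tinf) <= 5.0  # one grid step

    def test_failure_rate_one_flags_every_cell(self):
        _, truth = sd.make_curves(sd.SimConfig(seed=3, n_cells=20, failure_rate=1.0))
        assert all(truth.failed_cells.values())
        assert all(v is None for v in truth.true_inflection_times.values())

    def test_ground_truth_is_exhaustive(self):
        cfg = sd.SimConfig(seed=4, n_cells=15)
        df, truth = sd.make_curves(cfg)
        cells = set(df["cell_id"])
        assert set(truth.true_inflection_times) == cells
        assert set(truth.failed_cells) == cells
        assert len(cells) == 15


class TestMakeAssemblies:
    def test_zero_contamination_gives_single_source_assemblies(self):
        asm, truth = sd.make_assemblies(
            sd.SimConfig(seed=5, n_cells=10, contamination_fraction=0.0)
        )
        assert set(truth.true_sources) == set(asm)
        assert all(len(src) == 1 for src in truth.true_sources.values())

    def test_contaminated_assemblies_have_two_sources(self):
        _, truth = sd.make_assemblies(
            sd.SimConfig(seed=6, n_cells=10, contamination_fraction=1.0)
        )
        assert all(len(src) == 2 for src in truth.true_sources.values())

    def test_mixture_is_flagged_by_tetramer_screen(self):
        asm, truth = sd.make_assemblies(
            sd.SimConfig(seed=7, n_cells=6, contamination_fraction=1.0)
        )
        flags = [
            assembly_qc.contamination_screen(contigs)[0]
            for contigs in asm.values()
        ]
        assert sum(flags) >= 5  # near-perfect on maximally distinct sources

    def test_rejects_bad_fractions_and_tiny_genomes(self):
        with pytest.raises(ValueError):
            sd.SimConfig(seed=0, contamination_fraction=1.5)
        with pytest.raises(ValueError):
            sd.SimConfig(seed=0, genome_length=5000)


class TestMakeGeneSets:
    def test_identity_one_reproduces_parent(self):
        cfg = sd.SimConfig(
            seed=8, identity_targets=(1.0,), genes_per_target=3, n_novel_genes=0
        )
        catalog, queries, truth = sd.make_gene_sets(cfg)
        assert all(v == 1.0 for v in truth.true_identity.values())
        assert all(seq in catalog.values() for seq in queries.values())

    def test_exact_substitution_count(self):
        rng = np.random.default_rng(0)
        parent = sd._random_gene(rng, 900)
        mutant, realized = sd.mutate_to_identity(rng, parent, 0.90)
        diffs = sum(a != b for a, b in zip(parent, mutant))
        assert diffs == 90
        assert realized == pytest.approx(0.90)

    def test_every_query_has_truth_records(self):
        cfg = sd.SimConfig(seed=9)
        _, queries, truth = sd.make_gene_sets(cfg)
        assert set(truth.true_identity) == set(queries)
        assert set(truth.novel_genes) == set(queries)


class TestFileEmission:
    def test_outputs_are_byte_identical_across_runs(self, tmp_path):
        cfg = sd.SimConfig(seed=11, n_leaves=8, n_cells=6, catalog_size=10,
                           genes_per_target=2, n_novel_genes=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.write_outputs(cfg, str(d1))
        sd.write_outputs(cfg, str(d2))
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_ground_truth_json_loads(self, tmp_path):
        cfg = sd.SimConfig(seed=12, n_leaves=5, n_cells=4, catalog_size=10,
                           genes_per_target=1, n_novel_genes=1)
        sd.write_outputs(cfg, str(tmp_path / "o"))
        data = json.loads((tmp_path / "o" / "ground_truth.json").read_text())
        assert len(data["true_inflection_times"]) == 4
        assert len(data["true_sources"]) == 4
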