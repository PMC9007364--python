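"""Identity engine, greedy clustering, novelty labels and enrichment."""

import numpy as np
import pytest

from sagpick import catalog_novelty as cn, synthetic_data as sd


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSequenceIdentity:
    def test_equal_sequences(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 500)
        assert cn.sequence_identity(s, s) == 1.0

    def test_reverse_complement_matches(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 500)
        assert cn.sequence_identity(cn.revcomp(s), s) == 1.0
        assert cn.sequence_identity(cn.revcomp(s), s, both_strands=False) < 0.8

    def test_construction_pairs_match_substitution_identity(self):
        rng = np.random.default_rng(2)
        for target in (0.99, 0.95, 0.90):
            parent = random_seq(rng, 1000)
            mutant, realized = sd.mutate_to_identity(rng, parent, target)
            computed = cn.sequence_identity(mutant, parent)
            assert abs(computed - realized) <= 0.005

    def test_symmetric_on_equal_length_pairs(self):
        rng = np.random.default_rng(3)
        a, b = random_seq(rng, 400), random_seq(rng, 400)
        assert cn.sequence_identity(a, b) == cn.sequence_identity(b, a)

    def test_unrelated_sequences_score_low(self):
        rng = np.random.default_rng(4)
        a, b = random_seq(rng, 1000), random_seq(rng, 1000)
        assert cn.sequence_identity(a, b) < 0.60


class TestDereplicate:
    def test_identical_sequences_cluster(self):
        rng = np.random.default_rng(5)
        s = random_seq(rng, 300)
        out = cn.dereplicate([cn.GeneRecord("a", s), cn.GeneRecord("b", s)])
        assert out["b"] == out["a"]

    def test_96_clusters_90_does_not(self):
        rng = np.random.default_rng(6)
        parent = random_seq(rng, 1000)
        near, _ = sd.mutate_to_identity(rng, parent, 0.96)
        far, _ = sd.mutate_to_identity(rng, parent, 0.90)
        out = cn.dereplicate(
            [
                cn.GeneRecord("p", parent),
                cn.GeneRecord("near", near),
                cn.GeneRecord("far", far),
            ],
            identity=0.95,
        )
        assert out["near"] == out["p"]
        assert out["far"] == "far"

    def test_reverse_complement_joins_cluster(self):
        rng = np.random.default_rng(7)
        s = random_seq(rng, 400)
        out = cn.dereplicate(
            [cn.GeneRecord("fw", s), cn.GeneRecord("rc", cn.revcomp(s))]
        )
        assert out["rc"] == out["fw"]

    def test_empty_input(self):
        assert cn.dereplicate([]) == {}


class TestLabelNovelty:
    def test_identical_query_is_known(self):
        rng = np.random.default_rng(8)
        s = random_seq(rng, 500)
        labels = cn.label_novelty(
            [cn.GeneRecord("q", s)], [cn.GeneRecord("c", s)]
        )
        assert labels[0].best_identity == 1.0 and not labels[0].novel

    def test_90_percent_mutant_is_novel(self):
        rng = np.random.default_rng(9)
        parent = random_seq(rng, 1000)
        mutant, _ = sd.mutate_to_identity(rng, parent, 0.90)
        labels = cn.label_novelty(
            [cn.GeneRecord("q", mutant)], [cn.GeneRecord("c", parent)]
        )
        assert labels[0].novel

    def test_exactly_95_percent_is_novel(self):
        # the rule is "no matches ABOVE 95%": equality stays novel
        rng = np.random.default_rng(10)
        parent = random_seq(rng, 1000)
        mutant, realized = sd.mutate_to_identity(rng, parent, 0.95)
        assert realized == 0.95
        labels = cn.label_novelty(
            [cn.GeneRecord("q", mutant)], [cn.GeneRecord("c", parent)]
        )
        assert labels[0].best_identity == pytest.approx(0.95, abs=0.005)
        if labels[0].best_identity == 0.95:  # computed at the exact boundary
            assert labels[0].novel

    def test_fresh_gene_scores_background(self):
        rng = np.random.default_rng(11)
        catalog = [cn.GeneRecord(f"c{i}", random_seq(rng, 800)) for i in range(20)]
        labels = cn.label_novelty(
            [cn.GeneRecord("q", random_seq(rng, 1000))], catalog
        )
        assert labels[0].best_identity < 0.60
        assert labels[0].novel


class TestOverlapCounts:
    def lab(self, gid, novel):
        return cn.NoveltyLabel(gid, None, 0.0, novel)

    def test_all_novel_means_zero_shared(self):
        table = cn.overlap_counts(
            {"cat": [self.lab("g1", True), self.lab("g2", True)]}
        ).set_index("catalog")
        assert table.loc["cat", "n_known"] == 0

    def test_known_fraction_matches_construction(self):
        labels = [self.lab(f"g{i}", i >= 4) for i in range(10)]  # 40% known
        table = cn.overlap_counts({"cat": labels}).set_index("catalog")
        assert table.loc["cat", "frac_known"] == pytest.approx(0.4)

    def test_disjoint_catalogs_share_nothing(self):
        a = [self.lab("g1", False), self.lab("g2", True)]
        b = [self.lab("g1", True), self.lab("g2", False)]
        table = cn.overlap_counts({"A": a, "B": b}).set_index("catalog")
        assert table.loc["joint", "n_known"] == 0

    def test_mismatched_query_sets_rejected(self):
        with pytest.raises(ValueError):
            cn.overlap_counts(
                {"A": [self.lab("g1", True)], "B": [self.lab("g2", True)]}
            )


class TestEnrichment:
    def make_inputs(self, rng, n_genes=300, n_cats=10, force_cat=None):
        letters = [chr(65 + i) for i in range(n_cats)]
        genes, labels = [], []
        for i in range(n_genes):
            cats = frozenset(
                rng.choice(letters, size=int(rng.integers(1, 3)), replace=False)
            )
            novel = bool(rng.random() < 0.5)
            if force_cat is not None and force_cat in cats:
                novel = True
            genes.append(cn.GeneRecord(f"g{i}", "A" * 60, cats))
            labels.append(cn.NoveltyLabel(f"g{i}", None, 0.0, novel))
        return genes, labels

    def test_forced_category_is_enriched(self):
        rng = np.random.default_rng(12)
        genes, labels = self.make_inputs(rng, force_cat="A")
        rows = cn.enrichment_test(labels, genes, n_permutations=2000, seed=1)
        row = next(r for r in rows if r.category == "A")
        assert row.direction == "enriched" and row.q_value < 0.01

    def test_q_never_below_p(self):
        rng = np.random.default_rng(13)
        genes, labels = self.make_inputs(rng)
        rows = cn.enrichment_test(labels, genes, n_permutations=500, seed=2)
        assert all(r.q_value >= r.p_value - 1e-12 for r in rows)

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(14)
        genes, labels = self.make_inputs(rng, n_genes=10)
        with pytest.raises(ValueError):
            cn.enrichment_test(labels, genes, n_permutations=0, seed=0)
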