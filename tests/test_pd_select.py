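"""Phylogenetic diversity arithmetic and the three selection solvers."""

import math

import numpy as np
import pytest

from sagpick import pd_select as ps, synthetic_data as sd, trees
from conftest import random_instance


class TestPdOf:
    def test_star_tree_single_leaf(self, star3):
        assert ps.pd_of(star3, ["leaf1"]) == 1.0

    def test_star_tree_all_leaves(self, star3):
        assert ps.pd_of(star3, ["leaf1", "leaf2", "leaf3"]) == 6.0

    def test_caterpillar_path_union(self, caterpillar):
        assert ps.pd_of(caterpillar, ["A", "C"]) == 8.0  # 1 + 3 + 4

    def test_empty_set_and_unknown_label(self, caterpillar):
        assert ps.pd_of(caterpillar, []) == 0.0
        with pytest.raises(ValueError):
            ps.pd_of(caterpillar, ["Z"])

    def test_monotone_and_submodular_on_random_probes(self):
        rng = np.random.default_rng(0)
        tree = sd.make_tree(sd.SimConfig(seed=1, n_leaves=12))
        leaves = trees.leaf_labels(tree)
        for _ in range(100):
            k = int(rng.integers(1, 11))
            s = set(rng.choice(leaves, size=k, replace=False))
            extra = set(rng.choice(leaves, size=2, replace=False))
            t = s | extra
            assert ps.pd_of(tree, s) <= ps.pd_of(tree, t) + 1e-12
            x = leaves[int(rng.integers(len(leaves)))]
            if x in s or x in extra:
                continue
            gain_small = ps.pd_of(tree, s | {x}) - ps.pd_of(tree, s)
            gain_big = ps.pd_of(tree, t | {x}) - ps.pd_of(tree, t)
            assert gain_big <= gain_small + 1e-12


class TestBruteforce:
    def test_unconstrained_selects_everything(self, caterpillar):
        prob = ps.SelectionProblem(
            caterpillar, ("A", "B", "C"), {"A": 1, "B": 1, "C": 1},
            budget=math.inf, cap=3, anchored=False,
        )
        res = ps.solve_bruteforce(prob)
        assert res.chosen == ("A", "B", "C")
        assert res.pd == pytest.approx(10.0)

    def test_zero_budget_selects_nothing(self, caterpillar):
        prob = ps.SelectionProblem(
            caterpillar, ("A", "B", "C"), {"A": 1, "B": 1, "C": 1},
            budget=0.0, cap=3, anchored=False,
        )
        res = ps.solve_bruteforce(prob)
        assert res.chosen == () and res.pd == 0.0

    def test_refuses_large_instances(self):
        tree = sd.make_tree(sd.SimConfig(seed=2, n_leaves=25))
        leaves = trees.leaf_labels(tree)
        prob = ps.SelectionProblem(
            tree, tuple(leaves), {l: 1.0 for l in leaves}, cap=5, anchored=False
        )
        with pytest.raises(ValueError):
            ps.solve_bruteforce(prob)


class TestBuildIp:
    def test_variable_counts(self):
        tree = sd.make_tree(sd.SimConfig(seed=3, n_leaves=7))
        leaves = trees.leaf_labels(tree)
        prob = ps.SelectionProblem(
            tree, tuple(leaves), {l: 1.0 for l in leaves}, cap=3, anchored=False
        )
        ip = ps.build_ip(prob)
        n_edges = len(trees.edge_index(tree))
        assert len(ip.leaf_order) == 7
        assert len(ip.var_names) == 7 + n_edges

    def test_single_candidate_optimum_is_its_path(self, caterpillar):
        prob = ps.SelectionProblem(
            caterpillar, ("A",), {"A": 1.0}, budget=5.0, cap=1, anchored=False
        )
        res = ps.solve_exact(prob)
        assert res.pd == pytest.approx(ps.pd_of(caterpillar, ["A"]))

    def test_lp_relaxation_bounds_integer_optimum(self):
        for seed in range(20):
            prob = random_instance(seed, n_leaves=10)
            ip = ps.build_ip(prob)
            lp = ps.solve_relaxation(ip)
            res = ps.solve_exact(prob, tie_break=False)
            assert lp >= res.pd - 1e-6


class TestSolveExact:
    def test_matches_bruteforce_on_random_instances(self):
        for seed in range(25):
            prob = random_instance(seed, n_leaves=8)
            b = ps.solve_bruteforce(prob)
            e = ps.solve_exact(prob)
            assert abs(b.pd - e.pd) <= 1e-9
            assert b.chosen == e.chosen  # shared lexicographic tie-break
            ps.validate_result(prob, e)

    def test_cardinality_cap_on_large_pool(self):
        # 300 candidate placements on a reference tree, cap 150
        cfg = sd.SimConfig(seed=4, n_leaves=60, n_cells=300)
        from sagpick import phylo_gain as pg

        tree = sd.make_tree(cfg)
        pl = pg.placements_from_frame(sd.make_placements(cfg, tree))
        grafted = pg.graft(tree, pl)
        rng = np.random.default_rng(5)
        cands = tuple(p.sag_id for p in pl)
        prob = ps.SelectionProblem(
            grafted.tree,
            cands,
            {c: float(rng.uniform(10, 100)) for c in cands},
            cap=150,
            anchored=True,
        )
        res = ps.solve_exact(prob, tie_break=False)
        assert len(res.chosen) <= 150
        assert res.total_cost <= prob.budget
        ps.validate_result(prob, res)

    def test_second_placement_on_same_edge_adds_only_its_pendant(self):
        from sagpick import phylo_gain as pg

        base = trees.parse_newick("((A:1,B:2):3,C:4);")
        pl = [
            pg.Placement("S1", 2, 0.3, 0.6),
            pg.Placement("S2", 2, 0.7, 0.5),
        ]
        grafted = pg.graft(base, pl)
        prob = ps.SelectionProblem(
            grafted.tree, ("S1", "S2"), {"S1": 1.0, "S2": 1.0},
            cap=2, anchored=True,
        )
        res = ps.solve_exact(prob)
        assert res.pd == pytest.approx(1.1)  # the two pendants only
        marginal = ps.pd_of(grafted.tree, {"A", "B", "C", "S1", "S2"}) - ps.pd_of(
            grafted.tree, {"A", "B", "C", "S1"}
        )
        assert marginal == pytest.approx(0.5)

    def test_infinite_cost_candidates_never_chosen(self):
        tree = sd.make_tree(sd.SimConfig(seed=6, n_leaves=6))
        leaves = trees.leaf_labels(tree)
        cost = {l: 1.0 for l in leaves}
        cost[leaves[0]] = math.inf
        prob = ps.SelectionProblem(
            tree, tuple(leaves), cost, cap=6, anchored=False
        )
        for solver in (ps.solve_exact, ps.solve_greedy):
            res = solver(prob)
            assert leaves[0] not in res.chosen


class TestSolveGreedy:
    def test_unconstrained_uniform_cost_selects_all(self):
        tree = sd.make_tree(sd.SimConfig(seed=7, n_leaves=9))
        leaves = trees.leaf_labels(tree)
        prob = ps.SelectionProblem(
            tree, tuple(leaves), {l: 2.0 for l in leaves},
            budget=math.inf, cap=9, anchored=False,
        )
        res = ps.solve_greedy(prob)
        assert res.chosen == tuple(sorted(leaves))

    def test_uniform_cost_greedy_within_1_minus_1_over_e(self):
        for seed in range(25):
            prob = random_instance(seed, n_leaves=9)
            uniform = ps.SelectionProblem(
                prob.tree, prob.candidates, {c: 1.0 for c in prob.candidates},
                budget=math.inf, cap=prob.cap, anchored=False,
            )
            g = ps.solve_greedy(uniform)
            e = ps.solve_exact(uniform, tie_break=False)
            assert g.pd >= (1 - 1 / math.e) * e.pd - 1e-9

    def test_two_sweeps_beat_single_ratio_sweep(self):
        # one expensive high-PD leaf vs two cheap low-PD leaves: the
        # ratio sweep picks the cheap pair, the plain-PD sweep the big leaf
        tree = trees.parse_newick("(X:10,(Y:2,Z:2):0.1);")
        prob = ps.SelectionProblem(
            tree, ("X", "Y", "Z"), {"X": 10.0, "Y": 1.0, "Z": 1.0},
            budget=10.0, cap=3, anchored=False,
        )
        # ratio sweep takes the cheap pair (PD 4.1) and can no longer afford
        # X; the plain-PD sweep takes X (PD 10); best-of-two returns X
        res = ps.solve_greedy(prob)
        assert res.pd == pytest.approx(10.0)
        ps.validate_result(prob, res)

    def test_never_beats_exact(self):
        for seed in range(15):
            prob = random_instance(seed + 50, n_leaves=9)
            assert ps.solve_greedy(prob).pd <= ps.solve_exact(
                prob, tie_break=False
            ).pd + 1e-9
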