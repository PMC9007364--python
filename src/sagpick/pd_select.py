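"""Budgeted phylogenetic-diversity cell prioritization.

Given a rooted tree containing candidate leaves (cells placed on a reference
phylogeny), per-cell costs (time to amplification inflection, minutes), a
total cost budget B and a cardinality cap k, choose the candidate set that
maximizes Faith's phylogenetic diversity (PD) — the total branch length of
the union of root-to-leaf paths of the selection. This is the budgeted
Noah's Ark problem.

The integer-programming formulation follows the bipartite leaf/branch view:
a binary variable x_l per candidate leaf and y_e per edge, maximizing
sum(len_e * y_e) subject to y_e <= sum of x_l over leaves below e (an edge is
"active" only if a selected leaf lies below it), the budget and the cap. y
may be relaxed to [0,1]: with positive lengths it is integral at any optimum.

Reference leaves already in the tree can be treated as pre-selected
("anchored", the default): edges with a reference leaf below them are active
regardless of the selection, so candidates are scored purely by the marginal
branch length they add. Three solvers share the contract: an exhaustive
oracle (<= 20 candidates), an exact mixed-integer solve, and a two-sweep
greedy heuristic (marginal PD per unit cost, then plain marginal PD).

Tie-breaking is deterministic everywhere: among equal-PD optima the chosen
set with the lexicographically smallest sorted label tuple wins.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from . import trees

__all__ = [
    "SelectionProblem",
    "SelectionResult",
    "IntegerProgram",
    "pd_of",
    "solve_bruteforce",
    "build_ip",
    "solve_exact",
    "solve_greedy",
    "validate_result",
]

_EPS = 1e-9
BRUTEFORCE_LIMIT = 20


@dataclass(frozen=True)
class SelectionProblem:
    tree: dendropy.Tree
    candidates: Tuple[str, ...]
    cost: Mapping[str, float]
    budget: float = math.inf
    cap: int = 0
    anchored: bool = True

    def __post_init__(self) -> None:
        leaves = set(trees.leaf_labels(self.tree))
        cands = tuple(sorted(set(self.candidates)))
        unknown = set(cands) - leaves
        if unknown:
            raise ValueError(f"candidates not in tree: {sorted(unknown)[:5]}")
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if self.cap < 0:
            raise ValueError("cardinality cap must be >= 0")
        for c in cands:
            if c not in self.cost or self.cost[c] < 0:
                raise ValueError(f"candidate {c} needs a nonnegative cost")
        object.__setattr__(self, "candidates", cands)


@dataclass(frozen=True)
class SelectionResult:
    chosen: Tuple[str, ...]
    pd: float
    total_cost: float
    solver: str
    optimal: bool


@dataclass
class IntegerProgram:
    """Solver-agnostic (maximization) program: variables are the candidate
    leaves followed by the objective edges; x binary, y relaxable to [0,1]."""

    var_names: List[str]
    objective: np.ndarray  # maximize objective @ z
    a_ub: sp.csr_matrix  # a_ub @ z <= b_ub
    b_ub: np.ndarray
    integrality: np.ndarray  # 1 = integer, 0 = continuous
    lower: np.ndarray
    upper: np.ndarray
    leaf_order: List[str]
    edge_lengths: np.ndarray


# ---------------------------------------------------------------------------
# PD and the edge reduction


def pd_of(tree: dendropy.Tree, leaves: Sequence[str]) -> float:
    """Rooted PD: total branch length on the union of root-to-leaf paths."""
    want = set(leaves)
    if not want:
        return 0.0
    by_label = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }
    unknown = want - by_label.keys()
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)[:5]}")
    seen: Set[int] = set()
    total = 0.0
    for label in want:
        node = by_label[label]
        while node is not tree.seed_node and id(node) not in seen:
            seen.add(id(node))
            total += node.edge.length or 0.0
            node = node.parent_node
    return total


def _objective_edges(
    problem: SelectionProblem,
    selectable: Optional[Sequence[str]] = None,
) -> List[Tuple[float, FrozenSet[str]]]:
    """(length, selectable-leaves-below) for each edge the selection can turn
    on. Anchored mode drops edges that a non-candidate leaf already keeps
    active (judged against the FULL candidate set, so unaffordable candidates
    never count as anchors); edges with no selectable leaf below are dropped.
    """
    cand = set(problem.candidates)
    pickable = cand if selectable is None else set(selectable)
    result = []
    idx = trees.edge_index(problem.tree)
    below_map = trees.leaves_below(problem.tree)
    for i, edge in idx.items():
        below = below_map[i]
        if problem.anchored and (below - cand):
            continue
        picks_below = below & pickable
        if not picks_below:
            continue
        result.append((float(edge.length), frozenset(picks_below)))
    return result


def _finite_candidates(problem: SelectionProblem) -> List[str]:
    return [c for c in problem.candidates if math.isfinite(problem.cost[c])]


def _objective_value(
    edges: Sequence[Tuple[float, FrozenSet[str]]], chosen: Set[str]
) -> float:
    return sum(length for length, below in edges if below & chosen)


# ---------------------------------------------------------------------------
# brute-force oracle


def solve_bruteforce(problem: SelectionProblem) -> SelectionResult:
    """Exhaustive enumeration over feasible candidate subsets (oracle)."""
    cands = _finite_candidates(problem)
    if len(cands) > BRUTEFORCE_LIMIT:
        raise ValueError(
            f"brute force refuses > {BRUTEFORCE_LIMIT} candidates; use solve_exact"
        )
    # keep anchored semantics identical to the other solvers even though the
    # candidate list shrank: evaluate edges against the ORIGINAL problem
    edges = _objective_edges(problem)
    best: Tuple[float, Tuple[str, ...], float] = (0.0, (), 0.0)
    for size in range(0, min(problem.cap, len(cands)) + 1):
        for combo in itertools.combinations(sorted(cands), size):
            cost = sum(problem.cost[c] for c in combo)
            if cost > problem.budget:
                continue
            value = _objective_value(edges, set(combo))
            if value > best[0] + _EPS or (
                abs(value - best[0]) <= _EPS and combo < best[1]
            ):
                best = (value, combo, cost)
    return SelectionResult(best[1], best[0], best[2], "bruteforce", True)


# ---------------------------------------------------------------------------
# integer program


def build_ip(problem: SelectionProblem) -> IntegerProgram:
    cands = _finite_candidates(problem)
    if not cands:
        raise ValueError("no candidates with finite cost")
    edges = _objective_edges(problem, selectable=cands)
    n_x, n_y = len(cands), len(edges)
    leaf_pos = {c: i for i, c in enumerate(cands)}
    obj = np.zeros(n_x + n_y)
    lengths = np.array([length for length, _ in edges])
    obj[n_x:] = lengths

    rows, cols, vals = [], [], []
    b_ub = []
    r = 0
    for j, (_, below) in enumerate(edges):
        # y_e - sum_{l below e} x_l <= 0
        rows.append(r)
        cols.append(n_x + j)
        vals.append(1.0)
        for leaf in below:
            rows.append(r)
            cols.append(leaf_pos[leaf])
            vals.append(-1.0)
        b_ub.append(0.0)
        r += 1
    if math.isfinite(problem.budget):
        for c in cands:
            rows.append(r)
            cols.append(leaf_pos[c])
            vals.append(float(problem.cost[c]))
        b_ub.append(float(problem.budget))
        r += 1
    for c in cands:
        rows.append(r)
        cols.append(leaf_pos[c])
        vals.append(1.0)
    b_ub.append(float(problem.cap))
    r += 1

    a_ub = sp.csr_matrix(
        (vals, (rows, cols)), shape=(r, n_x + n_y)
    )
    integrality = np.concatenate([np.ones(n_x), np.zeros(n_y)])
    return IntegerProgram(
        var_names=[f"x:{c}" for c in cands] + [f"y:{j}" for j in range(n_y)],
        objective=obj,
        a_ub=a_ub,
        b_ub=np.array(b_ub),
        integrality=integrality,
        lower=np.zeros(n_x + n_y),
        upper=np.ones(n_x + n_y),
        leaf_order=list(cands),
        edge_lengths=lengths,
    )


def _milp_max(
    ip: IntegerProgram,
    fix_one: Set[str] = frozenset(),
    fix_zero: Set[str] = frozenset(),
) -> Tuple[Optional[float], Optional[Set[str]]]:
    lower = ip.lower.copy()
    upper = ip.upper.copy()
    pos = {c: i for i, c in enumerate(ip.leaf_order)}
    for c in fix_one:
        lower[pos[c]] = 1.0
    for c in fix_zero:
        upper[pos[c]] = 0.0
    res = milp(
        c=-ip.objective,
        constraints=LinearConstraint(ip.a_ub, -np.inf, ip.b_ub),
        integrality=ip.integrality,
        bounds=Bounds(lower, upper),
    )
    if not res.success:
        return None, None
    n_x = len(ip.leaf_order)
    chosen = {ip.leaf_order[i] for i in range(n_x) if res.x[i] > 0.5}
    return -res.fun, chosen


def solve_relaxation(ip: IntegerProgram) -> float:
    """LP relaxation bound (upper bound on the integer optimum)."""
    res = linprog(
        c=-ip.objective,
        A_ub=ip.a_ub,
        b_ub=ip.b_ub,
        bounds=list(zip(ip.lower, ip.upper)),
        method="highs",
    )
    if not res.success:
        raise RuntimeError("LP relaxation failed")
    return -res.fun


def solve_exact(
    problem: SelectionProblem, tie_break: bool = True
) -> SelectionResult:
    """Optimal selection via the mixed-integer program.

    With ``tie_break`` the lexicographically smallest optimal set is
    recovered by iteratively testing label fixings against the optimum
    (one extra solve per candidate in the worst case).
    """
    cands = _finite_candidates(problem)
    if not cands or problem.cap == 0:
        return SelectionResult((), 0.0, 0.0, "exact_ip", True)
    ip = build_ip(problem)
    opt, chosen = _milp_max(ip)
    if opt is None:  # cannot happen: the empty selection is always feasible
        raise RuntimeError("MILP solver failed on a feasible instance")
    tol = _EPS * max(1.0, abs(opt))
    if tie_break and chosen:
        fixed_in: Set[str] = set()
        fixed_out: Set[str] = set()
        edges = _objective_edges(problem, selectable=cands)
        for label in cands:
            if (
                _objective_value(edges, fixed_in) >= opt - tol
                and sum(problem.cost[c] for c in fixed_in) <= problem.budget
            ):
                break  # current prefix is itself optimal; smallest extension
            val, _ = _milp_max(ip, fix_one=fixed_in | {label}, fix_zero=fixed_out)
            if val is not None and val >= opt - tol:
                fixed_in.add(label)
            else:
                fixed_out.add(label)
        chosen = fixed_in
    chosen_t = tuple(sorted(chosen))
    edges = _objective_edges(problem, selectable=cands)
    return SelectionResult(
        chosen_t,
        _objective_value(edges, set(chosen_t)),
        sum(problem.cost[c] for c in chosen_t),
        "exact_ip",
        True,
    )


# ---------------------------------------------------------------------------
# greedy heuristic


def _greedy_sweep(
    problem: SelectionProblem,
    edges: Sequence[Tuple[float, FrozenSet[str]]],
    per_cost: bool,
) -> Tuple[Tuple[str, ...], float, float]:
    cands = _finite_candidates(problem)
    chosen: List[str] = []
    active = np.zeros(len(edges), dtype=bool)
    spent = 0.0
    remaining = set(cands)
    while remaining and len(chosen) < problem.cap:
        best_label, best_key = None, None
        for label in sorted(remaining):
            cost = problem.cost[label]
            if spent + cost > problem.budget:
                continue
            marginal = sum(
                length
                for j, (length, below) in enumerate(edges)
                if not active[j] and label in below
            )
            if marginal <= 0:
                continue
            key = marginal / cost if (per_cost and cost > 0) else (
                math.inf if per_cost else marginal
            )
            if per_cost and cost == 0:
                key = math.inf
            if best_key is None or key > best_key + _EPS:
                best_label, best_key = label, key
        if best_label is None:
            break
        chosen.append(best_label)
        remaining.discard(best_label)
        spent += problem.cost[best_label]
        for j, (_, below) in enumerate(edges):
            if best_label in below:
                active[j] = True
    value = _objective_value(edges, set(chosen))
    return tuple(sorted(chosen)), value, spent


def solve_greedy(problem: SelectionProblem) -> SelectionResult:
    """Best of two greedy sweeps: marginal-PD-per-cost and plain marginal PD."""
    edges = _objective_edges(problem, selectable=_finite_candidates(problem))
    a = _greedy_sweep(problem, edges, per_cost=True)
    b = _greedy_sweep(problem, edges, per_cost=False)
    pick = a
    if b[1] > a[1] + _EPS or (abs(b[1] - a[1]) <= _EPS and b[0] < a[0]):
        pick = b
    return SelectionResult(pick[0], pick[1], pick[2], "greedy", False)


# ---------------------------------------------------------------------------
# validation


def validate_result(problem: SelectionProblem, result: SelectionResult) -> None:
    """Re-derive PD, cost and cardinality; raise if anything disagrees."""
    if len(result.chosen) > problem.cap:
        raise AssertionError("cardinality cap violated")
    cost = sum(problem.cost[c] for c in result.chosen)
    if cost > problem.budget + _EPS:
        raise AssertionError("budget violated")
    if abs(cost - result.total_cost) > _EPS * max(1.0, cost):
        raise AssertionError("stored cost disagrees with recomputation")
    for c in result.chosen:
        if not math.isfinite(problem.cost[c]):
            raise AssertionError("infinite-cost candidate chosen")
    if problem.anchored:
        anchors = set(trees.leaf_labels(problem.tree)) - set(problem.candidates)
        expected = pd_of(problem.tree, anchors | set(result.chosen)) - pd_of(
            problem.tree, anchors
        )
    else:
        expected = pd_of(problem.tree, result.chosen)
    if abs(expected - result.pd) > 1e-6 * max(1.0, abs(expected)):
        raise AssertionError(
            f"stored PD {result.pd} disagrees with recomputed {expected}"
        )
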