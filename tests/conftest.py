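import numpy as np
import pytest

from sagpick import synthetic_data as sd
from sagpick import trees


@pytest.fixture
def caterpillar():
    """((A:1,B:2):3,C:4); — hand-checkable PD arithmetic."""
    return trees.parse_newick("((A:1,B:2):3,C:4);")


@pytest.fixture
def star3():
    return trees.parse_newick("(leaf1:1,leaf2:2,leaf3:3);")


def random_instance(seed, n_leaves=8, anchored=False):
    """A small random selection problem with random costs/budget/cap."""
    from sagpick import pd_select as ps

    rng = np.random.default_rng(seed)
    cfg = sd.SimConfig(seed=seed, n_leaves=n_leaves)
    tree = sd.make_tree(cfg)
    leaves = trees.leaf_labels(tree)
    cost = {l: float(rng.uniform(0.5, 10.0)) for l in leaves}
    return ps.SelectionProblem(
        tree=tree,
        candidates=tuple(leaves),
        cost=cost,
        budget=float(rng.uniform(3.0, 40.0)),
        cap=int(rng.integers(1, n_leaves + 1)),
        anchored=anchored,
    )
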