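import numpy as np
import pytest

import phylochem as pc


@pytest.fixture
def balanced4():
    """((A,B),(C,D)) with unit branches; ultrametric depth 2."""
    return pc.read_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def tree3():
    return pc.read_newick("((A:1,B:1):1,C:2):0;")


def balanced_tree(depth: int):
    """Fully balanced ultrametric tree with 2**depth tips, unit branches."""

    def build(level, offset):
        if level == 0:
            return f"T{offset}:1"
        left = build(level - 1, offset)
        right = build(level - 1, offset + 2 ** (level - 1))
        return f"({left},{right}):1"

    s = build(depth, 0)[: -2] + "0;"  # root edge length 0
    return pc.read_newick(s)


def caterpillar_tree(n: int):
    """Ladder tree with n tips, unit branches (not ultrametric)."""
    s = "(T0:1,T1:1)"
    for i in range(2, n):
        s = f"({s}:1,T{i}:1)"
    return pc.read_newick(s + ":0;")


def random_tree(n: int, seed: int):
    return pc.simulate_yule_tree(n, seed=seed)
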