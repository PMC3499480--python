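"""The D statistic: change sums, the two nulls, and D itself."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import phylochem as pc
from phylochem.dstat import compute_d, trait_seed_sequence
from phylochem.errors import MissingStateError, NotBifurcatingError, NullsIndistinguishableError

from conftest import balanced_tree, caterpillar_tree, random_tree


def s_obs_oracle(tree, states):
    """Independent brute force in exact rational arithmetic: every node
    value is recomputed from scratch by descending to the tips."""

    def node_value(nd):
        if nd.is_leaf():
            return Fraction(states[nd.taxon.label])
        left, right = nd.child_nodes()
        return (node_value(left) + node_value(right)) / 2

    total = Fraction(0)
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            left, right = nd.child_nodes()
            total += abs(node_value(left) - node_value(right))
    return float(total)


class TestObservedChanges:
    def test_clade_marker(self, balanced4):
        s = pc.observed_changes(balanced4, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert s == 1.0

    def test_dispersed_states(self, balanced4):
        s = pc.observed_changes(balanced4, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert s == 2.0

    def test_constant_trait_zero(self, balanced4):
        assert pc.observed_changes(balanced4, dict.fromkeys("ABCD", 1)) == 0.0

    def test_missing_state_raises(self, balanced4):
        with pytest.raises(MissingStateError):
            pc.observed_changes(balanced4, {"A": 1, "B": 0, "C": 1})

    def test_multifurcation_raises(self):
        t = pc.read_newick("(A:1,B:1,C:1):0;")
        with pytest.raises(NotBifurcatingError):
            pc.observed_changes(t, {"A": 1, "B": 0, "C": 0})

    def test_inversion_invariance(self):
        t = random_tree(16, 7)
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        rng = np.random.default_rng(7)
        states = {l: int(v) for l, v in zip(labels, rng.integers(0, 2, 16))}
        inverted = {l: 1 - v for l, v in states.items()}
        assert pc.observed_changes(t, states) == pytest.approx(
            pc.observed_changes(t, inverted)
        )

    def test_rotation_invariance(self, balanced4):
        rotated = pc.read_newick("((D:1,C:1):1,(B:1,A:1):1):0;")
        states = {"A": 1, "B": 0, "C": 1, "D": 1}
        assert pc.observed_changes(balanced4, states) == pc.observed_changes(
            rotated, states
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        t = random_tree(n, seed + 300)
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        states = {l: int(v) for l, v in zip(labels, rng.integers(0, 2, n))}
        assert pc.observed_changes(t, states) == s_obs_oracle(t, states)


class TestPermutationNull:
    def test_constant_trait_all_zero(self, balanced4):
        sr = pc.permutation_null(balanced4, dict.fromkeys("ABCD", 1), 50, seed=0)
        assert np.all(sr == 0)

    def test_converges_to_exhaustive_mean(self, balanced4):
        # all C(4,2)=6 placements of two 1s: two within-cherry (s=1),
        # four split (s=2); exhaustive mean 10/6
        states = {"A": 1, "B": 1, "C": 0, "D": 0}
        sr = pc.permutation_null(balanced4, states, 1000, seed=5)
        se = sr.std(ddof=1) / np.sqrt(sr.size)
        assert abs(sr.mean() - 10 / 6) <= 3 * se

    def test_determinism(self, balanced4):
        states = {"A": 1, "B": 1, "C": 0, "D": 0}
        a = pc.permutation_null(balanced4, states, 100, seed=9)
        b = pc.permutation_null(balanced4, states, 100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestBrownianNull:
    def test_exact_state_counts(self):
        t = random_tree(20, 3)
        from phylochem._flat import FlatTree
        from phylochem.dstat import brownian_tip_values, top_k_binary

        flat = FlatTree.from_dendropy(t)
        states = top_k_binary(
            brownian_tip_values(flat, 200, np.random.default_rng(0)), 7
        )
        assert np.all(states.sum(axis=1) == 7)

    def test_star_tree_matches_permutation_null(self):
        # on a star, Brownian tip values are i.i.d., so top-k sets are a
        # uniform k-subset: both nulls draw from the same distribution
        star = pc.read_newick("(" + ",".join(f"T{i}:1" for i in range(16)) + "):0;")
        star = pc.resolve_polytomies(star, seed=0)
        states = dict.fromkeys([f"T{i}" for i in range(16)], 0)
        for i in range(8):
            states[f"T{i}"] = 1
        sr = pc.permutation_null(star, states, 1000, seed=21)
        sb = pc.brownian_null(star, k=8, n_simulations=1000, seed=22)
        assert stats.ks_2samp(sr, sb).pvalue > 0.01

    def test_caterpillar_brownian_mean_below_permutation(self):
        t = caterpillar_tree(16)
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        states = {l: (1 if i < 8 else 0) for i, l in enumerate(labels)}
        sr = pc.permutation_null(t, states, 1000, seed=31)
        sb = pc.brownian_null(t, k=8, n_simulations=1000, seed=32)
        assert sb.mean() < sr.mean()

    def test_degenerate_k_rejected(self, balanced4):
        with pytest.raises(ValueError):
            pc.brownian_null(balanced4, k=0, n_simulations=10, seed=0)
        with pytest.raises(ValueError):
            pc.brownian_null(balanced4, k=4, n_simulations=10, seed=0)


class TestComputeD:
    def test_d_is_one_at_permutation_mean(self):
        sr = np.array([2.0, 4.0, 6.0])
        sb = np.array([1.0, 1.0, 1.0])
        res = compute_d("t", 10, 5, s_obs=4.0, sr_values=sr, sb_values=sb)
        assert res.d == pytest.approx(1.0)

    def test_d_is_zero_at_brownian_mean(self):
        sr = np.array([2.0, 4.0, 6.0])
        sb = np.array([0.5, 1.5])
        res = compute_d("t", 10, 5, s_obs=1.0, sr_values=sr, sb_values=sb)
        assert res.d == pytest.approx(0.0)

    def test_midpoint_arithmetic(self):
        res = compute_d("t", 10, 5, s_obs=5.0, sr_values=[7.0], sb_values=[3.0])
        assert res.d == pytest.approx(0.5)

    def test_p_value_conventions(self):
        sr = np.arange(1, 101, dtype=float)  # 1..100
        sb = np.arange(101, 201, dtype=float)
        res = compute_d("t", 10, 5, s_obs=10.0, sr_values=sr, sb_values=sb)
        assert res.p_random == pytest.approx(0.10)  # 10 of 100 at or below
        assert res.p_brownian == pytest.approx(1.0)  # all sb >= 10
        corr = compute_d(
            "t", 10, 5, s_obs=0.5, sr_values=sr, sb_values=sb, corrected=True
        )
        assert corr.p_random == pytest.approx(1 / 101)

    def test_indistinguishable_nulls_raise(self):
        with pytest.raises(NullsIndistinguishableError):
            compute_d("t", 10, 5, 1.0, [2.0, 2.0], [2.0, 2.0])


class TestPhyloD:
    def test_clade_marker_has_strong_signal(self):
        t = balanced_tree(6)  # 64 tips
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        states = {l: (1 if i < 32 else 0) for i, l in enumerate(labels)}
        res = pc.phylo_d(t, states, trait="marker", seed=4)
        assert res.s_obs == 1.0
        assert res.d < 0
        assert res.p_random < 0.05

    def test_random_traits_center_on_one(self):
        t = random_tree(128, 17)
        ds = []
        for i in range(40):
            states = pc.simulate_binary_trait(t, "random", 0.5, seed=1000 + i)
            ds.append(pc.phylo_d(t, states, trait=f"r{i}", n_permutations=300,
                                 n_simulations=300, seed=i).d)
        assert abs(np.mean(ds) - 1.0) < 0.15

    def test_inversion_same_permutation_null(self):
        t = random_tree(32, 5)
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        states = {l: (1 if i % 3 == 0 else 0) for i, l in enumerate(labels)}
        inverted = {l: 1 - v for l, v in states.items()}
        sr1 = pc.permutation_null(t, states, 200, seed=8)
        sr2 = pc.permutation_null(t, inverted, 200, seed=8)
        # shuffles of complementary state multisets give identical sums
        np.testing.assert_allclose(sr1, sr2)

    def test_seed_substreams_order_independent(self):
        t = random_tree(32, 6)
        labels = [lf.taxon.label for lf in t.leaf_node_iter()]
        states = {l: (1 if i % 2 else 0) for i, l in enumerate(labels)}
        r1 = pc.phylo_d(t, states, trait="x", n_permutations=100, n_simulations=100, seed=3)
        _ = pc.phylo_d(t, states, trait="y", n_permutations=100, n_simulations=100, seed=3)
        r2 = pc.phylo_d(t, states, trait="x", n_permutations=100, n_simulations=100, seed=3)
        assert r1.d == r2.d and r1.p_random == r2.p_random

    def test_trait_seed_sequence_distinct(self):
        a = trait_seed_sequence(1, "crinine").generate_state(2)
        b = trait_seed_sequence(1, "lycorine").generate_state(2)
        assert not np.array_equal(a, b)
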