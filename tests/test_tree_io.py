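"""Tree reading, patristic distances, pruning, polytomies, genus clades."""

import numpy as np
import pytest

import phylochem as pc
from phylochem.errors import DuplicateTipLabelError, NewickParseError

from conftest import random_tree


def patristic_oracle(tree):
    """Brute force: enumerate explicit root paths per tip and use
    d(i,j) = depth(i) + depth(j) - 2*depth(mrca)."""
    leaves = list(tree.leaf_node_iter())
    paths = {}
    for lf in leaves:
        p, nd = [], lf
        while nd is not None:
            p.append(nd)
            nd = nd.parent_node
        paths[lf.taxon.label] = p

    def depth_of(node):
        d, nd = 0.0, node
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        return d

    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa = paths[labels[i]]
            ids = {id(x) for x in pa}
            mrca = next(x for x in paths[labels[j]] if id(x) in ids)
            d = depth_of(pa[0]) + depth_of(paths[labels[j]][0]) - 2 * depth_of(mrca)
            D[i, j] = D[j, i] = d
    return labels, D


class TestReadNewick:
    def test_minimal_two_tip(self):
        t = pc.read_newick("(A:1,B:1):0;")
        assert sorted(lf.taxon.label for lf in t.leaf_node_iter()) == ["A", "B"]
        dm = pc.patristic_matrix(t)
        assert dm.values[dm.labels.index("A"), dm.labels.index("B")] == 2.0

    def test_three_tip_ultrametric(self, tree3):
        assert pc.is_ultrametric(tree3, rel_tol=1e-6)

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            pc.read_newick("((A:1,B")

    def test_duplicate_tip_label(self):
        with pytest.raises(DuplicateTipLabelError):
            pc.read_newick("((A:1,A:1):1,C:2):0;")

    def test_missing_lengths_default_to_unit(self):
        t = pc.read_newick("(A,B);")
        dm = pc.patristic_matrix(t)
        assert dm.values[0, 1] == 2.0

    def test_roundtrip(self, tree3):
        s = pc.write_newick(tree3)
        again = pc.read_newick(s)
        a = pc.patristic_matrix(tree3).submatrix(["A", "B", "C"])
        b = pc.patristic_matrix(again).submatrix(["A", "B", "C"])
        np.testing.assert_allclose(a.values, b.values)


class TestUltrametric:
    def test_unequal_depths(self):
        t = pc.read_newick("((A:1,B:1):1,C:5):0;")
        assert not pc.is_ultrametric(t)

    def test_within_tolerance(self):
        t = pc.read_newick("((A:1,B:1.0000001):1,C:2):0;")
        assert pc.is_ultrametric(t, rel_tol=1e-3)
        assert not pc.is_ultrametric(t, rel_tol=1e-12)


class TestPatristic:
    def test_hand_example(self, tree3):
        dm = pc.patristic_matrix(tree3)
        get = lambda a, b: dm.values[dm.labels.index(a), dm.labels.index(b)]
        assert get("A", "B") == 2.0
        assert get("A", "C") == 4.0
        assert get("B", "C") == 4.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_root_path_oracle(self, seed):
        t = random_tree(10, seed)
        labels, expected = patristic_oracle(t)
        dm = pc.patristic_matrix(t).submatrix(labels)
        np.testing.assert_allclose(dm.values, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_metric_triangle_inequality(self, seed):
        dm = pc.patristic_matrix(random_tree(12, seed + 50))
        D = dm.values
        n = D.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


class TestPrune:
    def test_keep_all_is_identity(self, tree3):
        p = pc.prune_to_tips(tree3, {"A", "B", "C"})
        a = pc.patristic_matrix(tree3).submatrix(["A", "B", "C"])
        b = pc.patristic_matrix(p).submatrix(["A", "B", "C"])
        np.testing.assert_allclose(a.values, b.values)

    def test_two_tip_distance_preserved(self, tree3):
        p = pc.prune_to_tips(tree3, {"A", "C"})
        dm = pc.patristic_matrix(p)
        assert dm.values[dm.labels.index("A"), dm.labels.index("C")] == 4.0

    @pytest.mark.parametrize("seed", range(5))
    def test_pruned_matrix_equals_submatrix(self, seed):
        t = random_tree(12, seed + 100)
        full = pc.patristic_matrix(t)
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(full.labels, size=6, replace=False))
        pruned = pc.patristic_matrix(pc.prune_to_tips(t, keep)).submatrix(keep)
        np.testing.assert_allclose(pruned.values, full.submatrix(keep).values, atol=1e-12)

    def test_errors(self, tree3):
        with pytest.raises(KeyError):
            pc.prune_to_tips(tree3, {"A", "Z"})
        with pytest.raises(ValueError):
            pc.prune_to_tips(tree3, {"A"})


class TestResolvePolytomies:
    def test_bifurcating_unchanged(self, balanced4):
        r = pc.resolve_polytomies(balanced4, seed=1)
        labels = sorted(["A", "B", "C", "D"])
        np.testing.assert_allclose(
            pc.patristic_matrix(r).submatrix(labels).values,
            pc.patristic_matrix(balanced4).submatrix(labels).values,
        )

    def test_trifurcation_zero_length_insertion(self):
        t = pc.read_newick("(A:1,B:1,C:1):0;")
        r = pc.resolve_polytomies(t, seed=3)
        internals = [nd for nd in r.preorder_node_iter() if not nd.is_leaf()]
        assert len(internals) == 2
        assert all(len(nd.child_nodes()) == 2 for nd in internals)
        dm = pc.patristic_matrix(r)
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(dm.values[iu], 2.0)

    def test_same_seed_same_topology(self):
        t = pc.read_newick("(A:1,B:1,C:1,D:1,E:1):0;")
        s1 = pc.write_newick(pc.resolve_polytomies(t, seed=7))
        s2 = pc.write_newick(pc.resolve_polytomies(t, seed=7))
        assert s1 == s2

    def test_distances_never_change(self):
        t = pc.read_newick("((A:1,B:1,C:1):2,(D:2,E:2,F:2,G:2):1):0;")
        labels = sorted("ABCDEFG")
        before = pc.patristic_matrix(t).submatrix(labels).values
        after = pc.patristic_matrix(pc.resolve_polytomies(t, seed=11)).submatrix(labels).values
        np.testing.assert_allclose(before, after, atol=1e-12)


class TestGenusClades:
    def test_monophyletic_genera(self):
        t = pc.read_newick("((A1:1,A2:1):1,(B1:1,B2:1):1):0;")
        gm = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        clades = pc.genus_clades(t, gm)
        assert {c.name: sorted(c.tips) for c in clades} == {
            "A": ["A1", "A2"],
            "B": ["B1", "B2"],
        }

    def test_fully_interleaved_polyphyly(self):
        t = pc.read_newick("((A1:1,B1:1):1,(A2:1,B2:1):1):0;")
        gm = {"A1": "A", "B1": "B", "A2": "A", "B2": "B"}
        clades = pc.genus_clades(t, gm)
        assert [(c.name, c.tips) for c in clades] == [
            ("A-1", ["A1"]),
            ("B-1", ["B1"]),
            ("A-2", ["A2"]),
            ("B-2", ["B2"]),
        ]
        # no same-genus pair has a pure MRCA: every clade is a singleton
        assert all(len(c.tips) == 1 for c in clades)

    def test_single_genus_whole_tree(self, balanced4):
        gm = {l: "G" for l in "ABCD"}
        clades = pc.genus_clades(balanced4, gm)
        assert len(clades) == 1 and sorted(clades[0].tips) == list("ABCD")

    def test_unmapped_tip_raises(self, balanced4):
        with pytest.raises(KeyError):
            pc.genus_clades(balanced4, {"A": "G"})

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_property(self, seed):
        t = pc.simulate_yule_tree(30, seed=seed, n_genera=8, polyphyly_fraction=0.3)
        gm = pc.tree_io.genus_map_from_labels(
            [lf.taxon.label for lf in t.leaf_node_iter()]
        )
        clades = pc.genus_clades(t, gm)
        tips = [tip for c in clades for tip in c.tips]
        assert sorted(tips) == sorted(gm)  # exact partition, no repeats
        for c in clades:
            assert {gm[t] for t in c.tips} == {c.genus}
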