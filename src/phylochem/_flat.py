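"""Array-backed tree representation for fast vectorised computations.

A :class:`FlatTree` freezes a rooted phylogeny into integer index arrays:
tips occupy node ids ``0 .. n_tips-1`` (in postorder encounter order),
internal nodes follow in postorder, with the root last.  All per-node
quantities (branch lengths, depths, Brownian values, ancestral averages)
become flat numpy arrays indexed by node id, so nulls with thousands of
draws reduce to a single Python loop over nodes with vector operations
across draws.
"""

from __future__ import annotations

import numpy as np

from .errors import NotBifurcatingError

__all__ = ["FlatTree"]


class FlatTree:
    """Immutable indexed view of a rooted tree.

    Parameters
    ----------
    tip_labels : list of str
        Labels for node ids ``0 .. n_tips-1``.
    parent : ndarray of int
        ``parent[i]`` is the node id of ``i``'s parent; ``-1`` for the root.
    children : list of list of int
        Child ids per node (empty for tips).
    blen : ndarray of float
        Branch length of the edge above each node; the root entry is 0.
    """

    def __init__(self, tip_labels, parent, children, blen):
        self.tip_labels = list(tip_labels)
        self.n_tips = len(self.tip_labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [list(c) for c in children]
        self.blen = np.asarray(blen, dtype=np.float64)
        self.n_nodes = len(self.parent)
        (root_candidates,) = np.nonzero(self.parent == -1)
        if len(root_candidates) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(root_candidates[0])
        self.tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        self._postorder = None
        self._preorder = None
        self._depth = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree) -> "FlatTree":
        """Flatten a dendropy Tree.  Missing edge lengths count as 0."""
        nodes = list(tree.postorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        ids = {}
        for i, nd in enumerate(tips):
            ids[id(nd)] = i
        for j, nd in enumerate(internals):
            ids[id(nd)] = len(tips) + j
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        blen = np.zeros(n_nodes)
        for nd in nodes:
            me = ids[id(nd)]
            if nd.parent_node is not None:
                parent[me] = ids[id(nd.parent_node)]
                blen[me] = nd.edge.length if nd.edge.length is not None else 0.0
            children[me] = [ids[id(c)] for c in nd.child_nodes()]
        labels = [
            (nd.taxon.label if nd.taxon is not None else "") for nd in tips
        ]
        return cls(labels, parent, children, blen)

    # -- traversals -------------------------------------------------------

    @property
    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents)."""
        if self._postorder is None:
            order = []
            stack = [self.root]
            while stack:
                nd = stack.pop()
                order.append(nd)
                stack.extend(self.children[nd])
            self._postorder = np.asarray(order[::-1], dtype=np.int64)
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        """Node ids in preorder (root first)."""
        if self._preorder is None:
            self._preorder = self.postorder[::-1].copy()
        return self._preorder

    @property
    def depth(self) -> np.ndarray:
        """Root-to-node path length per node (root = 0)."""
        if self._depth is None:
            d = np.zeros(self.n_nodes)
            for nd in self.preorder[1:]:
                d[nd] = d[self.parent[nd]] + self.blen[nd]
            self._depth = d
        return self._depth

    @property
    def is_bifurcating(self) -> bool:
        return all(
            len(c) == 2 for i, c in enumerate(self.children) if i >= self.n_tips
        )

    def internal_pairs(self):
        """(node id, left child, right child) for internal nodes, postorder.

        Raises NotBifurcatingError on any polytomy or unary node.
        """
        out = []
        for nd in self.postorder:
            c = self.children[nd]
            if not c:
                continue
            if len(c) != 2:
                raise NotBifurcatingError(
                    f"internal node with {len(c)} children; resolve polytomies first"
                )
            out.append((nd, c[0], c[1]))
        return out

    # -- distances --------------------------------------------------------

    def patristic(self) -> np.ndarray:
        """Pairwise tip-to-tip path-length matrix, rows/cols in tip-id order.

        Uses d(i, j) = depth(i) + depth(j) - 2 * depth(mrca(i, j)), merging
        tip sets bottom-up so every cross-child pair is charged exactly once
        at its most recent common ancestor.  Works on multifurcating trees.
        """
        n = self.n_tips
        depth = self.depth
        dist = np.zeros((n, n))
        below: dict[int, np.ndarray] = {
            i: np.asarray([i]) for i in range(n)
        }
        for nd in self.postorder:
            kids = self.children[nd]
            if not kids:
                continue
            sets = [below.pop(k) for k in kids]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    ia, ib = sets[a], sets[b]
                    d = depth[ia][:, None] + depth[ib][None, :] - 2.0 * depth[nd]
                    dist[np.ix_(ia, ib)] = d
                    dist[np.ix_(ib, ia)] = d.T
            below[nd] = np.concatenate(sets)
        return dist
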