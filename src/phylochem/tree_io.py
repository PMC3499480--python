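"""Reading, validating and transforming rooted phylogenies.

Trees are held as :class:`dendropy.Tree` objects (rooted as written) and
flattened to :class:`~phylochem._flat.FlatTree` index arrays for numeric
work.  Patristic distances are summed branch lengths along the unique
tip-to-tip path; on an ultrametric tree all tips are equidistant from the
root, which several genus-level shortcuts below rely on.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._flat import FlatTree
from .errors import DuplicateTipLabelError, NewickParseError

__all__ = [
    "DistanceMatrix",
    "GenusClade",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "is_ultrametric",
    "patristic_matrix",
    "prune_to_tips",
    "resolve_polytomies",
    "genus_clades",
    "genus_map_from_labels",
    "load_genus_map",
]


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal distance matrix over an ordered label set."""

    labels: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.units
        )

    def condensed(self) -> np.ndarray:
        """Strict upper triangle, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, units: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), units)


# ---------------------------------------------------------------------------
# newick I/O


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [t.label for t in tree.taxon_namespace]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DuplicateTipLabelError(f"duplicate tip label {lab!r}")
        seen.add(lab)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            # root edge defaults to 0, all others to unit length
            edge.length = 0.0 if edge.head_node is tree.seed_node else 1.0
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted tree from a Newick string.

    Missing branch lengths default to 1.0 (0 on the root edge).  Raises
    :class:`NewickParseError` with the parser's position information on
    malformed input and :class:`DuplicateTipLabelError` on repeated tips.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise DuplicateTipLabelError(str(exc)) from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return _validate(tree)


def read_newick_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialise to Newick (';'-terminated); writes to *path* if given."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    if not s.endswith(";"):
        s += ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


# ---------------------------------------------------------------------------
# queries and transforms


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip depths agree within rel_tol of the maximum."""
    flat = FlatTree.from_dendropy(tree)
    depths = flat.depth[: flat.n_tips]
    dmax = depths.max()
    if dmax == 0:
        return True
    return bool((dmax - depths.min()) <= rel_tol * dmax)


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Summed-branch-length distance between every pair of tips."""
    flat = FlatTree.from_dendropy(tree)
    return DistanceMatrix(flat.tip_labels, flat.patristic(), units="branch-length")


def prune_to_tips(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Induced subtree on *keep*; patristic distances among kept tips are
    unchanged (unary nodes suppressed with branch lengths summed)."""
    keep = set(keep)
    have = set(tip_labels(tree))
    unknown = keep - have
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to keep")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    pruned.is_rooted = True
    # collapse a remaining root unifurcation (root edge absorbs nothing
    # distance-wise between tips, but keep invariants tidy)
    seed = pruned.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0) + (seed.edge.length or 0.0)
        pruned.seed_node = child
        child.parent_node = None
        seed = child
    return pruned


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Strictly bifurcating copy; polytomies become seeded random caterpillars
    of zero-length internal branches, so no patristic distance changes."""
    out = tree.clone(depth=1)
    out.resolve_polytomies(limit=2, update_bipartitions=False, rng=random.Random(seed))
    for edge in out.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return out


# ---------------------------------------------------------------------------
# genus handling


@dataclass
class GenusClade:
    """A maximal clade whose tips all belong to one genus."""

    name: str  # genus, or genus-1/genus-2/... when polyphyletic
    genus: str
    tips: list[str] = field(default_factory=list)


def genus_map_from_labels(labels) -> dict[str, str]:
    """Derive genus from tip labels of the form ``Genus_species``."""
    return {lab: lab.split("_", 1)[0] for lab in labels}


def load_genus_map(path) -> dict[str, str]:
    """Read a 2-column CSV (tip,genus)."""
    df = pd.read_csv(path, header=None, names=["tip", "genus"], dtype=str)
    return dict(zip(df["tip"], df["genus"]))


def genus_clades(tree: dendropy.Tree, genus_map: dict[str, str]) -> list[GenusClade]:
    """Partition tips into maximal pure-genus clades, in preorder.

    A monophyletic genus yields one clade named after the genus; a
    polyphyletic genus yields one clade per maximal pure subtree, named
    ``genus-1``, ``genus-2``, ... in tree traversal order.
    """
    tips = tip_labels(tree)
    unmapped = [t for t in tips if t not in genus_map]
    if unmapped:
        raise KeyError(f"tips without a genus mapping: {unmapped}")

    # genus of a node's subtree if pure, else None (postorder fill)
    pure: dict[int, str | None] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            pure[id(nd)] = genus_map[nd.taxon.label]
        else:
            genera = {pure[id(c)] for c in nd.child_nodes()}
            pure[id(nd)] = genera.pop() if (len(genera) == 1 and None not in genera) else None

    clades: list[GenusClade] = []

    def collect(nd):
        if pure[id(nd)] is not None:
            members = [lf.taxon.label for lf in nd.leaf_iter()]
            clades.append(GenusClade(name="", genus=pure[id(nd)], tips=members))
            return
        for c in nd.child_nodes():
            collect(c)

    collect(tree.seed_node)

    counts: dict[str, int] = {}
    for cl in clades:
        counts[cl.genus] = counts.get(cl.genus, 0) + 1
    seen: dict[str, int] = {}
    for cl in clades:
        if counts[cl.genus] == 1:
            cl.name = cl.genus
        else:
            seen[cl.genus] = seen.get(cl.genus, 0) + 1
            cl.name = f"{cl.genus}-{seen[cl.genus]}"
    return clades
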