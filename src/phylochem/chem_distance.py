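"""Chemical-profile distances and genus-level aggregation.

The chemical distance between two taxa is the binary squared Euclidean
distance between their presence/absence vectors over the alkaloid-type
vocabulary — i.e. the number of types found in exactly one of the two
taxa (a Hamming mismatch count, in trait-count units).

Genus-level comparison aggregates species profiles to one profile per
pure-genus clade (elementwise union), and takes the phylogenetic
distance between clades from exemplar tips; on an ultrametric tree the
patristic distance between any cross-clade tip pair is the same, so the
exemplar choice does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tree_io
from .errors import VocabularyMismatchError
from .tree_io import DistanceMatrix, GenusClade

__all__ = [
    "ChemicalProfile",
    "profiles_from_matrix",
    "binary_squared_euclidean_matrix",
    "genus_profiles",
    "genus_distance_matrices",
]


@dataclass
class ChemicalProfile:
    """Presence/absence vector over a fixed alkaloid-type vocabulary."""

    label: str
    types: tuple[str, ...]
    vector: np.ndarray

    def __post_init__(self):
        self.types = tuple(self.types)
        self.vector = np.asarray(self.vector, dtype=np.int8)
        if self.vector.shape != (len(self.types),):
            raise ValueError("vector length does not match type vocabulary")
        if not np.all(np.isin(self.vector, (0, 1))):
            raise ValueError("profile entries must be 0/1")

    @property
    def present(self) -> set[str]:
        return {t for t, v in zip(self.types, self.vector) if v}


def profiles_from_matrix(matrix, traits=None) -> list[ChemicalProfile]:
    """One profile per species from a BinaryTraitMatrix.

    Uses the alkaloid columns by default; species with any missing value
    among the chosen traits are omitted (their profile is undefined).
    """
    if traits is None:
        traits = matrix.traits_of_kind("alkaloid")
    traits = tuple(traits)
    sub = matrix.data[list(traits)]
    out = []
    for sp, row in sub.iterrows():
        if row.isna().any():
            continue
        out.append(ChemicalProfile(sp, traits, row.to_numpy()))
    return out


def _stack(profiles) -> tuple[tuple[str, ...], np.ndarray, list[str]]:
    if not profiles:
        raise ValueError("no profiles given")
    vocab = profiles[0].types
    for p in profiles:
        if p.types != vocab:
            raise VocabularyMismatchError(
                f"profile {p.label!r} uses a different type vocabulary"
            )
    X = np.stack([p.vector for p in profiles]).astype(np.int16)
    return vocab, X, [p.label for p in profiles]


def binary_squared_euclidean_matrix(profiles) -> DistanceMatrix:
    """Pairwise mismatch counts between binary profiles.

    For 0/1 vectors the squared Euclidean distance equals the Hamming
    mismatch count: the number of types present in exactly one taxon.
    """
    _, X, labels = _stack(profiles)
    diff = (X[:, None, :] != X[None, :, :]).sum(axis=2)
    return DistanceMatrix(labels, diff.astype(float), units="trait-count")


def genus_profiles(profiles, clades: list[GenusClade]) -> list[ChemicalProfile]:
    """Aggregate species profiles to one per clade by elementwise union.

    Polyphyletic genera contribute one profile per retained clade, under
    the clade's ``genus-1``/``genus-2`` name.
    """
    by_label = {p.label: p for p in profiles}
    vocab = profiles[0].types if profiles else ()
    out = []
    for cl in clades:
        missing = [t for t in cl.tips if t not in by_label]
        if missing:
            raise KeyError(f"clade {cl.name!r} members without a profile: {missing}")
        vecs = np.stack([by_label[t].vector for t in cl.tips])
        out.append(ChemicalProfile(cl.name, vocab, vecs.max(axis=0)))
    return out


def genus_distance_matrices(
    tree,
    clades: list[GenusClade],
    profiles,
    rel_tol: float = 1e-6,
    force: bool = False,
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Genus-level (phylogenetic, chemical) distance matrices over clades.

    The phylogenetic distance between two clades is the patristic distance
    between their exemplar tips (lexicographically first member).  This is
    exemplar-independent only on ultrametric trees, so non-ultrametric
    input raises unless ``force=True``.
    """
    if not force and not tree_io.is_ultrametric(tree, rel_tol=rel_tol):
        raise ValueError(
            "tree is not ultrametric; genus distances are exemplar-dependent "
            "(pass force=True to override)"
        )
    full = tree_io.patristic_matrix(tree)
    idx = {lab: i for i, lab in enumerate(full.labels)}
    exemplars = [min(cl.tips) for cl in clades]
    rows = [idx[e] for e in exemplars]
    phylo = full.values[np.ix_(rows, rows)].copy()
    np.fill_diagonal(phylo, 0.0)
    labels = [cl.name for cl in clades]
    phylo_dm = DistanceMatrix(labels, phylo, units=full.units)
    gp = genus_profiles(profiles, clades)
    chem_dm = binary_squared_euclidean_matrix(gp)
    return phylo_dm, chem_dm
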