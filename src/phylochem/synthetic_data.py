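"""Synthetic study generator: trees and traits with known signal structure.

Emulates the structure of a chemotaxonomic survey of a plant clade:
an ultrametric pure-birth (Yule) phylogeny of ~108 species in ~43
genera (some polyphyletic), nine alkaloid-type presence/absence traits
of which two are singletons (found in one species each) and seven are
informative, and two bioassay activity traits coupled to the chemistry.

Phylogenetic signal is parameterised as a Brownian/random mixture: each
informative trait is drawn from the Brownian threshold model with
probability ``w`` (its signal level) and from a uniform random k-subset
otherwise.  These two generators are exactly the two endpoints that
define the D statistic, so the long-run expected D interpolates from 1
(w = 0) to 0 (w = 1), giving recovery tests analytically known anchors.

Bioassay traits are Brownian-threshold draws accepted only when they
overlap a designated anchor alkaloid (Jaccard similarity above a floor),
mimicking activity driven by the underlying chemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import dendropy
import numpy as np
import pandas as pd

from ._flat import FlatTree
from .dstat import brownian_tip_values, top_k_binary, trait_seed_sequence
from .trait_coding import BinaryTraitMatrix
from . import tree_io

__all__ = [
    "StudyConfig",
    "simulate_yule_tree",
    "simulate_binary_trait",
    "simulate_profiles",
    "simulate_study",
    "write_study",
]


@dataclass
class StudyConfig:
    """Parameters of one synthetic study.

    Defaults mirror the emulated survey: 108 species across 43 genera
    (a tenth of them polyphyletic), nine recorded alkaloid types with two
    singletons, and two bioassay traits (AChE, SERT) anchored to alkaloid
    types with known matching activity.
    """

    n_species: int = 108
    n_genera: int = 43
    polyphyly_fraction: float = 0.1
    birth_rate: float = 1.0
    informative_types: tuple[str, ...] = (
        "crinine",
        "galanthamine",
        "galanthindole",
        "homolycorine",
        "lycorine",
        "montanine",
        "tazettine",
    )
    singleton_types: tuple[str, ...] = ("belladine", "cherylline")
    alkaloid_prevalence: tuple[float, ...] = (0.30, 0.25, 0.10, 0.20, 0.40, 0.15, 0.35)
    signal: float | tuple[float, ...] = 0.3  # mixture weight w per informative trait
    bioassay_names: tuple[str, ...] = ("AChE", "SERT")
    bioassay_prevalence: tuple[float, ...] = (0.40, 0.25)
    bioassay_anchor: tuple[str, ...] = ("galanthamine", "crinine")
    bioassay_overlap_floor: float = 0.25
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self):
        ws = self.signal_levels()
        if any(not (0.0 <= w <= 1.0) for w in ws):
            raise ValueError("signal levels must lie in [0, 1]")
        if any(not (0.0 < p < 1.0) for p in self.alkaloid_prevalence):
            raise ValueError("prevalences must lie in (0, 1)")
        if len(self.alkaloid_prevalence) != len(self.informative_types):
            raise ValueError("one prevalence per informative type required")
        if len(self.singleton_types) >= self.n_alkaloid_types:
            raise ValueError("singletons must be fewer than alkaloid types")
        if len(self.bioassay_prevalence) != len(self.bioassay_names):
            raise ValueError("one prevalence per bioassay required")
        if len(self.bioassay_anchor) != len(self.bioassay_names):
            raise ValueError("one anchor alkaloid per bioassay required")
        for a in self.bioassay_anchor:
            if a not in self.informative_types:
                raise ValueError(f"anchor {a!r} is not an informative alkaloid type")

    @property
    def n_alkaloid_types(self) -> int:
        return len(self.informative_types) + len(self.singleton_types)

    def signal_levels(self) -> tuple[float, ...]:
        if isinstance(self.signal, (int, float)):
            return tuple(float(self.signal) for _ in self.informative_types)
        return tuple(float(w) for w in self.signal)


# ---------------------------------------------------------------------------
# tree simulation


def _clade_blocks(tree, n_genera: int, rng: np.random.Generator) -> np.ndarray:
    """Partition leaves (in leaf order) into ``n_genera`` clade blocks.

    Starts from the root and repeatedly splits a randomly chosen block
    (weight proportional to size - 1) into its two children until the
    target count is reached.  Every block is a clade, so painted genera
    are monophyletic before any forced polyphyly.
    """
    leaves = list(tree.leaf_node_iter())
    pos = {id(lf): i for i, lf in enumerate(leaves)}
    size = {}
    for nd in tree.postorder_node_iter():
        size[id(nd)] = 1 if nd.is_leaf() else sum(size[id(c)] for c in nd.child_nodes())
    blocks = [tree.seed_node]
    while len(blocks) < n_genera:
        weights = np.asarray([size[id(b)] - 1 for b in blocks], dtype=float)
        total = weights.sum()
        if total == 0:
            break  # all blocks are single leaves
        i = int(rng.choice(len(blocks), p=weights / total))
        nd = blocks.pop(i)
        blocks.extend(nd.child_nodes())
    block_of = np.empty(len(leaves), dtype=int)
    ordered = sorted(blocks, key=lambda b: min(pos[id(lf)] for lf in b.leaf_iter()))
    for g, b in enumerate(ordered):
        for lf in b.leaf_iter():
            block_of[pos[id(lf)]] = g
    return block_of


def _paint_genera(
    tree, n_genera: int, polyphyly_fraction: float, rng: np.random.Generator
) -> list[str]:
    """Genus per leaf-order position: clade blocks plus forced polyphyly.

    Polyphyly is forced by reassigning one tip from a donor genus at
    least two blocks away (in leaf order) to each selected target genus:
    the MRCA of the target then spans a foreign block, so the genus
    cannot be monophyletic.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if not (2 <= n_genera <= n_tips):
        raise ValueError("need 2 <= n_genera <= n_tips")
    block_of = _clade_blocks(tree, n_genera, rng)
    n_genera = int(block_of.max()) + 1
    genus_of = block_of.copy()
    n_poly = int(round(polyphyly_fraction * n_genera))
    if n_poly:
        targets = rng.choice(n_genera, size=min(n_poly, n_genera), replace=False)
        for tgt in targets:
            counts = np.bincount(genus_of, minlength=n_genera)
            donors = [
                i
                for i in range(n_tips)
                if abs(block_of[i] - tgt) >= 2
                and genus_of[i] == block_of[i]  # not already moved
                and genus_of[i] not in targets
                and counts[genus_of[i]] >= 2
            ]
            if not donors:
                continue
            genus_of[donors[rng.integers(len(donors))]] = tgt
    return [f"Genus{g:02d}" for g in genus_of]


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    n_genera: int | None = None,
    polyphyly_fraction: float = 0.0,
) -> dendropy.Tree:
    """Ultrametric bifurcating tree from a pure-birth process.

    Tip labels take the form ``Genus{g}_sp{s}``; genera are painted on
    contiguous leaf-order blocks, with ``polyphyly_fraction`` of them made
    polyphyletic by grafting in one distant tip's label.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.edge.length = 0.0
    birth_time: dict[int, float] = {}
    t = 0.0
    active = []
    for _ in range(2):
        child = root.new_child()
        birth_time[id(child)] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        nd = active.pop(int(rng.integers(len(active))))
        nd.edge.length = t - birth_time[id(nd)]
        for _ in range(2):
            child = nd.new_child()
            birth_time[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for nd in active:
        nd.edge.length = t - birth_time[id(nd)]

    leaves = list(tree.leaf_node_iter())
    if n_genera is None:
        n_genera = max(2, int(round(n_tips * 0.4)))
    genera = _paint_genera(tree, n_genera, polyphyly_fraction, rng)
    counters: dict[str, int] = {}
    ns = tree.taxon_namespace
    for leaf, genus in zip(leaves, genera):
        counters[genus] = counters.get(genus, 0) + 1
        leaf.taxon = ns.new_taxon(f"{genus}_sp{counters[genus]:02d}")
    return tree


# ---------------------------------------------------------------------------
# trait simulation


def _prevalence_to_k(prevalence: float, n: int) -> int:
    k = int(round(prevalence * n))
    if not (1 <= k <= n - 1):
        raise ValueError(
            f"prevalence {prevalence} gives degenerate state count k={k} at n={n}"
        )
    return k


def simulate_binary_trait(
    tree, model: str, prevalence: float, seed=None
) -> dict[str, int]:
    """One binary trait with exactly round(prevalence * n) state-1 tips.

    ``model='brownian_threshold'``: Brownian tip values, top-k set to 1
    (maximal clumping consistent with the prevalence, in expectation).
    ``model='random'``: uniform k-subset of tips (no signal).
    """
    flat = tree if isinstance(tree, FlatTree) else FlatTree.from_dendropy(tree)
    k = _prevalence_to_k(prevalence, flat.n_tips)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model == "brownian_threshold":
        tips = brownian_tip_values(flat, 1, rng)
        states = top_k_binary(tips, k)[0]
    elif model == "random":
        states = np.zeros(flat.n_tips, dtype=np.int8)
        states[rng.choice(flat.n_tips, size=k, replace=False)] = 1
    else:
        raise ValueError(f"unknown trait model {model!r}")
    return dict(zip(flat.tip_labels, (int(v) for v in states)))


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.sum((a + b) > 0)
    if union == 0:
        return 1.0
    return float(np.sum((a * b) > 0) / union)


def simulate_profiles(tree, config: StudyConfig):
    """Draw the full trait matrix for one study and record the truth.

    Informative alkaloid traits are Brownian-threshold with probability
    equal to their signal level, else random; singleton types get exactly
    one carrier; bioassay traits are Brownian-threshold draws retried
    until their Jaccard overlap with the anchor alkaloid reaches the
    configured floor.  Every model choice and seed goes into the truth
    record.
    """
    flat = FlatTree.from_dendropy(tree)
    n = flat.n_tips
    labels = flat.tip_labels
    columns: dict[str, np.ndarray] = {}
    truth: dict[str, dict] = {}

    ws = config.signal_levels()
    for name, prev, w in zip(config.informative_types, config.alkaloid_prevalence, ws):
        rng = np.random.default_rng(trait_seed_sequence(config.seed, name))
        model = "brownian_threshold" if rng.random() < w else "random"
        k = min(max(_prevalence_to_k(prev, n), 2), n - 2)
        if model == "brownian_threshold":
            states = top_k_binary(brownian_tip_values(flat, 1, rng), k)[0]
        else:
            states = np.zeros(n, dtype=np.int8)
            states[rng.choice(n, size=k, replace=False)] = 1
        columns[name] = states
        truth[name] = {"kind": "alkaloid", "model": model, "w": w, "k": int(k)}

    for name in config.singleton_types:
        rng = np.random.default_rng(trait_seed_sequence(config.seed, name))
        states = np.zeros(n, dtype=np.int8)
        states[int(rng.integers(n))] = 1
        columns[name] = states
        truth[name] = {"kind": "alkaloid", "model": "singleton", "k": 1}

    for name, prev, anchor in zip(
        config.bioassay_names, config.bioassay_prevalence, config.bioassay_anchor
    ):
        rng = np.random.default_rng(trait_seed_sequence(config.seed, name))
        k = min(max(_prevalence_to_k(prev, n), 2), n - 2)
        anchor_states = columns[anchor]
        states = None
        for attempt in range(1, config.max_retries + 1):
            cand = top_k_binary(brownian_tip_values(flat, 1, rng), k)[0]
            if _jaccard(cand, anchor_states) >= config.bioassay_overlap_floor:
                states = cand
                break
        if states is None:
            raise RuntimeError(
                f"could not satisfy overlap floor {config.bioassay_overlap_floor} "
                f"for {name} vs {anchor} in {config.max_retries} draws"
            )
        columns[name] = states
        truth[name] = {
            "kind": "bioassay",
            "model": "brownian_threshold",
            "k": int(k),
            "anchor": anchor,
            "jaccard": _jaccard(states, anchor_states),
            "attempts": attempt,
        }

    data = pd.DataFrame({name: col for name, col in columns.items()}, index=labels)
    kinds = {name: truth[name]["kind"] for name in columns}
    genus = tree_io.genus_map_from_labels(labels)
    matrix = BinaryTraitMatrix(data, kinds, genus)
    record = {"config": asdict(config), "traits": truth}
    return matrix, record


def simulate_study(config: StudyConfig):
    """Tree + trait matrix + truth record for one configured study."""
    tree = simulate_yule_tree(
        config.n_species,
        birth_rate=config.birth_rate,
        seed=config.seed,
        n_genera=config.n_genera,
        polyphyly_fraction=config.polyphyly_fraction,
    )
    matrix, truth = simulate_profiles(tree, config)
    return tree, matrix, truth


def write_study(config: StudyConfig, out_dir) -> dict[str, str]:
    """Write tree.nwk, traits.csv and truth.json; byte-stable per config."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    tree, matrix, truth = simulate_study(config)
    paths = {
        "tree": os.path.join(out_dir, "tree.nwk"),
        "traits": os.path.join(out_dir, "traits.csv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    tree_io.write_newick(tree, paths["tree"])
    matrix.to_csv(paths["traits"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
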