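"""Phylogenetic signal in binary traits: the D statistic.

D standardises the observed amount of phylogenetic dispersion in a binary
trait between two analytically meaningful endpoints:

    D = (s_obs - mean(s_b)) / (mean(s_r) - mean(s_b))

where s_obs is the sister-clade difference sum of the observed states,
s_r are difference sums under random tip shuffles that preserve the
number of state-1 tips k, and s_b are difference sums under a Brownian
threshold model (a continuous character diffuses along the tree; the k
tips with the largest values are assigned state 1).  D = 1 means the
trait looks shuffled (no signal); D = 0 means it is clumped exactly as
Brownian evolution predicts; D < 0 is stronger clumping, D > 1
overdispersion.

The difference sum assigns each tip its 0/1 state, gives every internal
node the unweighted mean of its two children (postorder), and adds up
the absolute differences between the two children of every internal
node.  Branch lengths play no role in the sum itself; they enter only
through the Brownian simulation, whose per-branch increments have
variance equal to branch length.  The identical statistic is applied to
the observation and to both nulls, which is what lets D self-normalise.

Significance is one-tailed from the null samples themselves:
``p_random`` = fraction of s_r <= s_obs (small s_obs = more structure
than shuffling), ``p_brownian`` = fraction of s_b >= s_obs (large s_obs
= overdispersed relative to Brownian motion).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from ._flat import FlatTree
from .errors import MissingStateError, NullsIndistinguishableError

__all__ = [
    "DResult",
    "observed_changes",
    "permutation_null",
    "brownian_null",
    "compute_d",
    "phylo_d",
]

DEFAULT_PERMUTATIONS = 1000
DEFAULT_SIMULATIONS = 1000


@dataclass
class DResult:
    """All Eq.-level quantities for one trait."""

    trait: str
    n_tips: int
    k: int  # number of state-1 tips
    s_obs: float
    sr_values: np.ndarray = field(repr=False)
    sb_values: np.ndarray = field(repr=False)
    mean_sr: float
    mean_sb: float
    d: float
    p_random: float  # P(D = 1): trait indistinguishable from shuffled
    p_brownian: float  # P(D = 0): trait indistinguishable from Brownian
    seed: int | None = None

    def row(self) -> dict:
        """Report row with the conventional column semantics."""
        return {
            "trait": self.trait,
            "n": self.n_tips,
            "k": self.k,
            "s_obs": self.s_obs,
            "mean_sr": self.mean_sr,
            "mean_sb": self.mean_sb,
            "D": self.d,
            "P(D=1)": self.p_random,
            "P(D=0)": self.p_brownian,
        }


# ---------------------------------------------------------------------------
# helpers


def _as_flat(tree) -> FlatTree:
    if isinstance(tree, FlatTree):
        return tree
    return FlatTree.from_dendropy(tree)


def _state_vector(flat: FlatTree, states) -> np.ndarray:
    """Map a tip->state mapping (or aligned array) to tip-id order."""
    if isinstance(states, dict):
        missing = [l for l in flat.tip_labels if l not in states]
        if missing:
            raise MissingStateError(f"tips without a state: {missing[:5]}")
        vec = np.asarray([states[l] for l in flat.tip_labels], dtype=float)
    else:
        vec = np.asarray(states, dtype=float)
        if vec.shape != (flat.n_tips,):
            raise ValueError("state vector length does not match tip count")
    if np.any(np.isnan(vec)):
        raise MissingStateError("NaN state encountered")
    if not np.all(np.isin(vec, (0.0, 1.0))):
        raise ValueError("states must be 0/1")
    return vec


def changes_batch(flat: FlatTree, states: np.ndarray) -> np.ndarray:
    """Sister-clade difference sums for a (draws x n_tips) state matrix."""
    states = np.atleast_2d(np.asarray(states, dtype=np.float64))
    m = states.shape[0]
    vals = np.empty((m, flat.n_nodes))
    vals[:, : flat.n_tips] = states
    s = np.zeros(m)
    for node, left, right in flat.internal_pairs():
        vl = vals[:, left]
        vr = vals[:, right]
        vals[:, node] = 0.5 * (vl + vr)
        s += np.abs(vl - vr)
    return s


def brownian_tip_values(flat: FlatTree, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Brownian tip values, (n_draws x n_tips); root at 0, unit rate.

    Zero-length branches contribute zero variance (degenerate increments),
    as arise from polytomy resolution.
    """
    if np.any(flat.blen < 0):
        raise ValueError("negative branch length")
    sd = np.sqrt(flat.blen)
    incr = rng.standard_normal((n_draws, flat.n_nodes)) * sd
    vals = np.empty((n_draws, flat.n_nodes))
    pre = flat.preorder
    vals[:, pre[0]] = 0.0
    parent = flat.parent
    for nd in pre[1:]:
        vals[:, nd] = vals[:, parent[nd]] + incr[:, nd]
    return vals[:, : flat.n_tips]


def top_k_binary(values: np.ndarray, k: int) -> np.ndarray:
    """Assign state 1 to the k largest entries of each row."""
    values = np.atleast_2d(values)
    out = np.zeros(values.shape, dtype=np.int8)
    if k == 0:
        return out
    idx = np.argpartition(-values, k - 1, axis=1)[:, :k]
    np.put_along_axis(out, idx, 1, axis=1)
    return out


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# public operations


def observed_changes(tree, states) -> float:
    """Observed difference sum s_obs of a binary trait on a bifurcating tree."""
    flat = _as_flat(tree)
    vec = _state_vector(flat, states)
    return float(changes_batch(flat, vec[None, :])[0])


def permutation_null(
    tree, states, n_permutations: int = DEFAULT_PERMUTATIONS, seed=None
) -> np.ndarray:
    """Difference sums under uniform shuffles of the observed tip states.

    Each draw permutes the multiset of states across tips (preserving k)
    and recomputes the difference sum; the mean of the result is s_r-bar.
    """
    flat = _as_flat(tree)
    vec = _state_vector(flat, states)
    rng = _rng(seed)
    mat = np.tile(vec, (n_permutations, 1))
    mat = rng.permuted(mat, axis=1)
    return changes_batch(flat, mat)


def brownian_null(
    tree, k: int, n_simulations: int = DEFAULT_SIMULATIONS, seed=None
) -> np.ndarray:
    """Difference sums under the Brownian threshold model at prevalence k/n.

    Per draw: simulate Brownian motion along the tree (root 0, increment
    variance = branch length), give state 1 to the k tips with the largest
    values, and record the difference sum.  The rank-based assignment
    enforces the observed state counts exactly.
    """
    flat = _as_flat(tree)
    if not (0 < k < flat.n_tips):
        raise ValueError(f"k must be strictly between 0 and {flat.n_tips}")
    if flat.depth[: flat.n_tips].max() <= 0:
        raise ValueError("tree has zero total depth; Brownian null undefined")
    flat.internal_pairs()  # fail fast on polytomies
    rng = _rng(seed)
    tips = brownian_tip_values(flat, n_simulations, rng)
    states = top_k_binary(tips, k)
    return changes_batch(flat, states)


def compute_d(
    trait: str,
    n_tips: int,
    k: int,
    s_obs: float,
    sr_values: np.ndarray,
    sb_values: np.ndarray,
    seed=None,
    corrected: bool = False,
) -> DResult:
    """Assemble D and its two one-tailed p-values from the null samples.

    With ``corrected=True`` p-values use (count+1)/(n+1) so they are never 0.
    """
    sr_values = np.asarray(sr_values, dtype=float)
    sb_values = np.asarray(sb_values, dtype=float)
    if sr_values.size == 0 or sb_values.size == 0:
        raise ValueError("null samples must be nonempty")
    mean_sr = float(sr_values.mean())
    mean_sb = float(sb_values.mean())
    denom = mean_sr - mean_sb
    scale = max(1.0, abs(mean_sr), abs(mean_sb))
    if abs(denom) < 1e-9 * scale:
        raise NullsIndistinguishableError(
            "permutation and Brownian null means coincide; D undefined"
        )
    d = (s_obs - mean_sb) / denom
    n_r, n_b = sr_values.size, sb_values.size
    c_r = int(np.sum(sr_values <= s_obs))
    c_b = int(np.sum(sb_values >= s_obs))
    if corrected:
        p_random = (c_r + 1) / (n_r + 1)
        p_brownian = (c_b + 1) / (n_b + 1)
    else:
        p_random = c_r / n_r
        p_brownian = c_b / n_b
    return DResult(
        trait=trait,
        n_tips=n_tips,
        k=k,
        s_obs=float(s_obs),
        sr_values=sr_values,
        sb_values=sb_values,
        mean_sr=mean_sr,
        mean_sb=mean_sb,
        d=float(d),
        p_random=float(p_random),
        p_brownian=float(p_brownian),
        seed=seed,
    )


def trait_seed_sequence(master_seed: int, trait: str) -> np.random.SeedSequence:
    """Deterministic per-trait substream, independent of execution order."""
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(trait.encode("utf-8"))]
    )


def phylo_d(
    tree,
    states_or_matrix,
    trait: str | None = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    n_simulations: int = DEFAULT_SIMULATIONS,
    seed: int = 0,
    corrected: bool = False,
) -> DResult:
    """Full D analysis of one binary trait on a bifurcating tree.

    ``states_or_matrix`` is a tip->0/1 mapping, an aligned 0/1 vector, or a
    BinaryTraitMatrix (then ``trait`` selects the column and species with a
    missing value are excluded by the caller via reconciliation).  Both
    nulls draw from deterministic substreams of ``seed`` keyed by the trait
    name, so per-trait results do not depend on analysis order.
    """
    flat = _as_flat(tree)
    states = states_or_matrix
    if hasattr(states_or_matrix, "states"):  # BinaryTraitMatrix
        if trait is None:
            raise ValueError("trait name required with a trait matrix")
        states = states_or_matrix.states(trait)
    name = trait if trait is not None else "trait"
    vec = _state_vector(flat, states)
    k = int(vec.sum())
    s_obs = observed_changes(flat, vec)
    ss = trait_seed_sequence(seed, name)
    ss_perm, ss_bm = ss.spawn(2)
    sr = permutation_null(flat, vec, n_permutations, np.random.default_rng(ss_perm))
    sb = brownian_null(flat, k, n_simulations, np.random.default_rng(ss_bm))
    return compute_d(
        name, flat.n_tips, k, s_obs, sr, sb, seed=seed, corrected=corrected
    )
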