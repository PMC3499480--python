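"""Mantel matrix-permutation test.

Correlates two distance matrices over the same taxa: the observed
statistic is the Pearson product-moment correlation r of their strict
upper triangles, and the null distribution is generated by applying a
random taxon permutation simultaneously to the rows and columns of the
second matrix and recomputing r.  The default p-value is one-tailed for
positive association with the (count+1)/(permutations+1) correction, so
p is never exactly 0; the uncorrected plain fraction and two-sided or
negative tails are available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np

from .errors import LabelMismatchError, ZeroVarianceError
from .tree_io import DistanceMatrix

__all__ = ["MantelResult", "mantel_test", "exhaustive_mantel"]

_TIE_EPS = 1e-12


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    n: int
    seed: int | None = None
    tail: str = "greater"
    exhaustive: bool = False

    def row(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "n_taxa": self.n,
        }


def _check_pair(A: DistanceMatrix, B: DistanceMatrix, min_n: int = 4):
    if list(A.labels) != list(B.labels):
        raise LabelMismatchError("distance matrices must share labels and order")
    if A.n < min_n:
        raise ValueError(f"need at least {min_n} taxa, got {A.n}")
    a = A.condensed()
    b = B.condensed()
    if a.std() == 0 or b.std() == 0:
        raise ZeroVarianceError("constant upper triangle; correlation undefined")
    return a, b


def _standardise(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _tail_count(null_r: np.ndarray, r_obs: float, tail: str) -> int:
    if tail == "greater":
        return int(np.sum(null_r >= r_obs - _TIE_EPS))
    if tail == "less":
        return int(np.sum(null_r <= r_obs + _TIE_EPS))
    if tail == "two-sided":
        return int(np.sum(np.abs(null_r) >= abs(r_obs) - _TIE_EPS))
    raise ValueError(f"unknown tail {tail!r}")


def mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    n_permutations: int = 999,
    seed=None,
    tail: str = "greater",
    corrected: bool = True,
) -> MantelResult:
    """Permutation test of association between two distance matrices.

    Rows and columns of B are permuted jointly ``n_permutations`` times;
    p is the (corrected) fraction of null correlations at least as
    extreme as the observed one in the direction of *tail*.
    """
    a, b = _check_pair(A, B)
    n = A.n
    iu = np.triu_indices(n, k=1)
    az = _standardise(a)
    r_obs = float(np.mean(az * _standardise(b)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Bv = B.values
    null_r = np.empty(n_permutations)
    for i in range(n_permutations):
        p = rng.permutation(n)
        bp = Bv[np.ix_(p, p)][iu]
        null_r[i] = np.mean(az * _standardise(bp))
    count = _tail_count(null_r, r_obs, tail)
    if corrected:
        pval = (count + 1) / (n_permutations + 1)
    else:
        pval = count / n_permutations
    return MantelResult(
        r=r_obs,
        p=float(pval),
        n_permutations=n_permutations,
        n=n,
        seed=seed if isinstance(seed, int) else None,
        tail=tail,
    )


def exhaustive_mantel(
    A: DistanceMatrix, B: DistanceMatrix, tail: str = "greater"
) -> MantelResult:
    """Exact Mantel p over all n! joint row/column permutations (n <= 7).

    Serves as the oracle for the sampled test: p is the plain fraction of
    permutations (the identity included) whose correlation is at least as
    extreme as the observed one.
    """
    a, b = _check_pair(A, B, min_n=3)
    n = A.n
    if n > 7:
        raise ValueError("exhaustive enumeration limited to n <= 7")
    iu = np.triu_indices(n, k=1)
    az = _standardise(a)
    r_obs = float(np.mean(az * _standardise(b)))
    Bv = B.values
    null_r = np.empty(math.factorial(n))
    for i, perm in enumerate(_iter_permutations(range(n))):
        p = np.asarray(perm)
        bp = Bv[np.ix_(p, p)][iu]
        null_r[i] = np.mean(az * _standardise(bp))
    count = _tail_count(null_r, r_obs, tail)
    pval = count / null_r.size
    return MantelResult(
        r=r_obs,
        p=float(pval),
        n_permutations=null_r.size,
        n=n,
        tail=tail,
        exhaustive=True,
    )
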