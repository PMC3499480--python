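"""Binary trait matrices: alkaloid presence/absence and binarised bioassays.

Alkaloid chemistry is coded per species as presence (1) / absence (0) of
each structural type from an 18-type controlled vocabulary (types defined
by hypothesised biosynthetic pathway).  Bioassay activity (AChE
inhibition, SERT binding) is binarised from screening percentages and
follow-up IC50 values: a species is active only if it passes the initial
screen AND its IC50 falls under the activity cutoff.

Traits carried by fewer than two species in either state are excluded
from signal analysis — D needs variation in both states for its nulls to
be non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReconciliationError
from . import tree_io

__all__ = [
    "ALKALOID_TYPES",
    "BinaryTraitMatrix",
    "BioassayRecord",
    "BIOASSAY_RULES",
    "load_trait_table",
    "code_bioactivity",
    "informative_traits",
    "reconcile",
]

# Controlled vocabulary of alkaloid structural types (18 biosynthetic
# classes); any given survey typically records only a subset.
ALKALOID_TYPES = (
    "norbelladine",
    "belladine",
    "cherylline",
    "crinine",
    "haemanthamine",
    "galanthamine",
    "galanthindole",
    "graciline",
    "homolycorine",
    "ismine",
    "lycorine",
    "montanine",
    "narciclasine",
    "pallidiflorine",
    "plicamine",
    "secoplicamine",
    "augustamine",
    "tazettine",
)

BIOASSAY_NAMES = ("AChE", "SERT")

# Screening-stage pass rules: AChE requires at least 50% enzyme inhibition
# at 1.0 ug/ml extract; SERT requires more than 85% transporter binding at
# 5 mg/ml.  Either way the confirmation stage requires IC50 < 50 ug/ml.
BIOASSAY_RULES = {
    "AChE": {
        "screen_min": 50.0,
        "screen_strict": False,  # >= 50 passes
        "screen_conc": 1.0,
        "screen_conc_unit": "ug/ml",
        "ic50_max": 50.0,
    },
    "SERT": {
        "screen_min": 85.0,
        "screen_strict": True,  # must exceed 85
        "screen_conc": 5.0,
        "screen_conc_unit": "mg/ml",
        "ic50_max": 50.0,
    },
}


@dataclass
class BioassayRecord:
    """One species' raw screening result for one assay."""

    species: str
    assay: str  # "AChE" | "SERT"
    screening_value: float | None  # % inhibition / % binding
    screening_concentration: float
    concentration_unit: str = "ug/ml"
    ic50: float | None = None  # ug/ml

    def __post_init__(self):
        if self.screening_value is not None and not (
            0.0 <= self.screening_value <= 100.0
        ):
            raise ValueError(
                f"screening percentage {self.screening_value} outside [0, 100]"
            )
        if self.screening_concentration <= 0:
            raise ValueError("screening concentration must be positive")
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError("IC50 must be positive")


def code_bioactivity(record: BioassayRecord, rules: dict | None = None):
    """Binarise a bioassay record: 1 active, 0 inactive, None missing.

    Active requires both the screening criterion and IC50 below the
    cutoff.  A failed screen or an IC50 at/above the cutoff gives 0.  An
    absent screening value — or a passed screen with no follow-up IC50 —
    gives missing.
    """
    rules = rules if rules is not None else BIOASSAY_RULES
    if record.assay not in rules:
        raise KeyError(f"unknown assay {record.assay!r}")
    r = rules[record.assay]
    if record.screening_value is None:
        return None
    passed = (
        record.screening_value > r["screen_min"]
        if r["screen_strict"]
        else record.screening_value >= r["screen_min"]
    )
    if not passed:
        return 0
    if record.ic50 is None:
        return None
    return 1 if record.ic50 < r["ic50_max"] else 0


# ---------------------------------------------------------------------------
# trait matrix


class BinaryTraitMatrix:
    """Species x trait 0/1 table with per-trait kind tags and missing mask.

    Internally a float DataFrame where NaN marks missing; accessors return
    clean integer views.
    """

    def __init__(self, data: pd.DataFrame, kinds: dict[str, str], genus: dict[str, str] | None = None):
        data = data.astype(float)
        vals = data.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0))
        if not ok.all():
            bad = vals[~ok][0]
            raise ValueError(f"non-binary value {bad!r} in trait matrix")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate species row {dup!r}")
        unknown = set(data.columns) - set(kinds)
        if unknown:
            raise KeyError(f"traits without a kind tag: {sorted(unknown)}")
        self.data = data
        self.kinds = {c: kinds[c] for c in data.columns}
        self.genus = dict(genus) if genus else None

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def traits_of_kind(self, kind: str) -> list[str]:
        return [t for t in self.traits if self.kinds[t] == kind]

    def states(self, trait: str) -> dict[str, int]:
        """Non-missing tip->state mapping for one trait."""
        col = self.data[trait].dropna()
        return {sp: int(v) for sp, v in col.items()}

    def present_count(self, trait: str) -> int:
        return int(self.data[trait].sum(skipna=True))

    def subset_species(self, species) -> "BinaryTraitMatrix":
        sub = self.data.loc[list(species)]
        genus = (
            {s: self.genus[s] for s in species if s in self.genus}
            if self.genus
            else None
        )
        return BinaryTraitMatrix(sub, self.kinds, genus)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        if self.genus:
            out.insert(0, "genus", [self.genus.get(s, "") for s in out.index])
        out.index.name = "species"
        out.to_csv(path)


def load_trait_table(path, schema: dict | None = None) -> BinaryTraitMatrix:
    """Read a species x trait CSV into a BinaryTraitMatrix.

    Column 1 is the species id, an optional ``genus`` column follows, and
    remaining columns are traits.  *schema* declares trait kinds:
    ``{"alkaloids": [...], "bioassays": [...]}``; by default any column in
    the alkaloid controlled vocabulary is an alkaloid and any in
    {AChE, SERT} a bioassay; other columns are rejected.  Empty cells are
    missing.
    """
    df = pd.read_csv(path, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    genus = None
    if "genus" in df.columns:
        genus = df["genus"].astype(str).to_dict()
        df = df.drop(columns=["genus"])
    if schema is None:
        schema = {"alkaloids": list(ALKALOID_TYPES), "bioassays": list(BIOASSAY_NAMES)}
    kinds: dict[str, str] = {}
    for t in schema.get("alkaloids", []):
        kinds[t] = "alkaloid"
    for t in schema.get("bioassays", []):
        kinds[t] = "bioassay"
    unknown = [c for c in df.columns if c not in kinds]
    if unknown:
        raise KeyError(f"unknown trait columns (not in schema): {unknown}")
    return BinaryTraitMatrix(df, kinds, genus)


# ---------------------------------------------------------------------------
# filtering and reconciliation


@dataclass
class TraitExclusion:
    trait: str
    reason: str
    n_present: int
    n_absent: int


def informative_traits(matrix: BinaryTraitMatrix):
    """Split traits into (kept, excluded-with-reasons).

    Kept iff at least two species carry each state among non-missing
    entries; singletons and invariant traits cannot support a signal test.
    """
    kept: list[str] = []
    excluded: list[TraitExclusion] = []
    for t in matrix.traits:
        col = matrix.data[t].dropna()
        n1 = int(col.sum())
        n0 = int(len(col) - n1)
        if n1 >= 2 and n0 >= 2:
            kept.append(t)
        else:
            if n1 <= 1:
                reason = (
                    "absent everywhere" if n1 == 0 else "present in a single species"
                )
            else:
                reason = (
                    "present everywhere" if n0 == 0 else "absent in a single species"
                )
            excluded.append(TraitExclusion(t, reason, n1, n0))
    return kept, excluded


@dataclass
class Reconciliation:
    """Tree/matrix alignment with per-trait pruning for missing values."""

    tree: object  # dendropy.Tree over the common species
    matrix: BinaryTraitMatrix
    common_species: list[str]
    dropped_from_tree: list[str]  # tips with no matrix row
    dropped_from_matrix: list[str]  # rows with no tip
    trait_species: dict[str, list[str]] = field(default_factory=dict)
    _trait_trees: dict[str, object] = field(default_factory=dict, repr=False)

    def tree_for(self, trait: str):
        """Tree pruned to the species with a non-missing value for *trait*."""
        if trait not in self._trait_trees:
            keep = self.trait_species[trait]
            if set(keep) == set(self.common_species):
                self._trait_trees[trait] = self.tree
            else:
                self._trait_trees[trait] = tree_io.prune_to_tips(self.tree, keep)
        return self._trait_trees[trait]

    def pruned_for(self, trait: str) -> list[str]:
        return sorted(set(self.common_species) - set(self.trait_species[trait]))


def reconcile(matrix: BinaryTraitMatrix, tree) -> Reconciliation:
    """Align a trait matrix with a tree on their common species.

    Tips without a trait row (and rows without a tip) are dropped from all
    analyses; species missing a particular trait's value are dropped only
    from that trait's analysis tree.
    """
    tips = tree_io.tip_labels(tree)
    common = [t for t in tips if t in set(matrix.species)]
    if len(common) < 4:
        raise ReconciliationError(
            f"only {len(common)} species shared between tree and matrix (need >= 4)"
        )
    dropped_tree = sorted(set(tips) - set(common))
    dropped_matrix = sorted(set(matrix.species) - set(common))
    sub = matrix.subset_species(common)
    pruned = tree_io.prune_to_tips(tree, common) if dropped_tree else tree
    trait_species = {
        t: [sp for sp in common if not np.isnan(sub.data.at[sp, t])]
        for t in sub.traits
    }
    return Reconciliation(
        tree=pruned,
        matrix=sub,
        common_species=common,
        dropped_from_tree=dropped_tree,
        dropped_from_matrix=dropped_matrix,
        trait_species=trait_species,
    )
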