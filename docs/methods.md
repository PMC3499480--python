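# Methods

## The D statistic

D measures phylogenetic signal in a binary trait by placing the
observed amount of trait dispersion between two reference points that
are themselves estimated by simulation on the same tree with the same
statistic.

**Change sum.**  For a rooted, strictly bifurcating tree, every tip is
assigned its 0/1 state and every internal node the unweighted mean of
its two daughters, computed in postorder.  The change sum is the total
of the absolute differences between the two daughters of each internal
node.  A trait confined to one clade produces a single large contrast
near that clade's root (sum 1 for a perfect clade marker); a trait
scattered over the tips produces many tip-level contrasts.  Branch
lengths do not enter the recursion; they matter only through the
Brownian simulation.  Because the identical statistic is applied to the
observation and to both nulls, D self-normalises: any alternative
change-count convention applied consistently would rescale numerator
and denominator together.

**Permutation null.**  Tip states are shuffled uniformly, preserving
the number k of state-1 tips; the mean change sum over 1000 draws is
`s̄_r`.  This is the "no signal" endpoint, D = 1.

**Brownian threshold null.**  A continuous character starts at 0 at the
root and gains an independent normal increment of variance equal to the
branch length along every branch; the k tips with the largest values
receive state 1.  The mean change sum over 1000 draws is `s̄_b`, the
"signal exactly as Brownian divergence" endpoint, D = 0.  The rank
(top-k) construction enforces the observed state counts exactly, which
is equivalent to solving for a numeric threshold for continuous values
(ties have probability zero on branches of positive length).  Root
state and diffusion rate need no estimation: a location shift or global
rescaling of the tip values leaves the top-k set unchanged.
Zero-length branches (introduced by polytomy resolution) contribute
zero variance; their degenerate increments are permitted, and the rare
exact ties they can create are broken deterministically by the
partition order, identically across all draws.

**D and p-values.**  D = (s_obs − s̄_b)/(s̄_r − s̄_b).  If the two null
means coincide (within 1e-9 relative tolerance) the statistic is
undefined and the code raises rather than returning a ratio of noise —
this occurs on trees with no resolving structure (e.g. pure star
trees, where both nulls are the same distribution).  P(D=1) is the
fraction of permutation change sums at or below the observed sum;
P(D=0) the fraction of Brownian change sums at or above it.  Both are
one-tailed, matching the decision rule "95% or more of the null sample
beyond the observation"; the plain fraction is the default and a
(count+1)/(n+1) correction is available by flag.  Whether a two-tailed
convention was ever intended by earlier users of the statistic is not
decidable from its usual description; the one-tailed rule is stated in
the report footer so readers are not left guessing.

**Reproducibility.**  One master seed per analysis; each trait draws
its null streams from a substream keyed by the CRC-32 of the trait
name, so per-trait results are identical in any execution order.

## Trees

Newick input is parsed as rooted; missing branch lengths default to 1
(0 on the root edge).  Ultrametricity is *validated* (default relative
tolerance 1e-6) but never enforced by transformation: dating a tree is
a modelling exercise in its own right and out of scope, and the genus
exemplar shortcut below refuses non-ultrametric input instead of
silently returning exemplar-dependent numbers.  Polytomies are resolved
into seeded random caterpillars of zero-length branches before D is
computed — this leaves every patristic distance unchanged while making
the two-daughter recursion well defined — and the report's provenance
block records whether resolution was triggered.  Patristic distances
are computed from node depths via d(i,j) = depth(i) + depth(j) −
2·depth(mrca), merging tip sets bottom-up.

## Trait coding

Bioassay activity is binarised in two stages mirroring standard
screening practice: an initial percentage screen (AChE: at least 50%
inhibition at 1.0 µg/ml; SERT: more than 85% binding at 5 mg/ml)
followed by IC50 confirmation (< 50 µg/ml counts as active).  A failed
screen codes 0.  A passed screen whose IC50 lands at or above the
cutoff codes 0 rather than missing: the follow-up measurement was made
and spoke against activity.  A passed screen with *no* IC50 measurement
codes missing — activity can neither be confirmed nor denied.

Traits are excluded from signal analysis unless at least two species
carry each state among non-missing entries.  This is deliberately
symmetric and slightly stronger than excluding single-carrier traits
only: D's nulls are degenerate whenever either state is (near-)fixed,
and a trait absent in a single species is exactly as uninformative as
one present in a single species.

Reconciliation is per trait: species missing one assay's value are
pruned from that assay's analysis tree only, leaving every other
trait's sample intact; tips without any trait row (and rows without a
tip) are dropped globally.  All drops are listed in the report.

## Chemical distances and genus aggregation

The distance between two binary profiles is the binary squared
Euclidean distance — identical to the Hamming mismatch count, the
number of alkaloid types present in exactly one of the two taxa.  Genus
profiles are the elementwise union of the member species' profiles:
"the genus makes a type if any sampled member does".  A count-sum
aggregation would change the metric and is intentionally not the
default (the union is what a binary downstream distance can consume);
the aggregation is a config point in `genus_profiles` callers.  Genus
clades are maximal subtrees whose tips all belong to one genus;
polyphyletic genera therefore contribute one row per clade, named
`genus-1`, `genus-2`, … in preorder.  The phylogenetic distance between
clades uses exemplar tips (lexicographically first member), valid
because on an ultrametric tree every cross-clade tip pair shares the
same MRCA depth; the code checks ultrametricity and requires an
explicit override otherwise.  Genera represented by a single species
are retained at genus level.

## Mantel tests

Pearson product-moment correlation of the strict upper triangles; the
null permutes rows and columns of the second matrix jointly, 999 times
by default.  The default p is one-tailed for positive association with
the (count+1)/(permutations+1) correction, so the smallest reachable p
at 999 permutations is 0.001 — a p such as 0.002 on a 999-permutation
grid is only expressible under this corrected convention, which is why
it is the default; the uncorrected fraction and other tails are flags.
An exhaustive enumerator over all n! permutations (n ≤ 7) serves as the
oracle in tests.  Tie comparisons use a 1e-12 tolerance so that exact
re-achievements of the observed correlation are counted.

## Synthetic studies

The generator reproduces the *structure* the pipeline assumes, with
every default chosen once to mirror the emulated survey: 108 species in
43 genera on an ultrametric Yule tree (birth rate 1; D and the Mantel
tests are invariant to tree-wide rescaling), nine alkaloid types of
which two are singletons and seven informative, and two bioassay
traits.  Genus labels are painted on clade blocks obtained by
recursively splitting the tree (split probability proportional to block
size), so genera are monophyletic except for a configurable fraction
(default 0.1) made polyphyletic by reassigning one tip from a genus at
least two blocks away — the intervening foreign tips guarantee the
target genus cannot be monophyletic.

Informative-trait prevalences (0.10–0.40 across the seven types) span
the occupancy range plausible for alkaloid types recorded in a minority
to a plurality of species; each trait is drawn from the Brownian
threshold model with probability w (default 0.3, placing expected D =
1 − w ≈ 0.7 in the moderate-signal regime) and from the uniform
k-subset model otherwise.  Bioassay traits (prevalence 0.40 and 0.25)
are Brownian-threshold draws accepted only when their Jaccard overlap
with an anchor alkaloid (galanthamine for AChE, crinine for SERT —
types with matching known pharmacology) reaches 0.25, mimicking
chemistry-driven activity; the accepted draw's overlap and attempt
count go into the truth record.

What the generator does **not** emulate: intraspecific variation and
detection-limit censoring in chemical profiling, correlated gain/loss
of types sharing biosynthetic precursors, non-Yule tree shape
(extinction, sampling biases), and measurement error in bioassays.
Passing tests therefore certify the statistical machinery under the
stated generating models, not robustness of inference to those
real-data complications.

## Problem sizes and numerical choices

Endpoint-recovery and calibration checks run on 128-tip trees at the
full 1000/1000 null draws (200 traits per endpoint, 500 per
calibration arm in the test suite; the standalone results script uses
100 and 200).  Mantel size and power use 999 permutations with 200–500
replicates at 30–100 taxa.  Change-sum computations are exact in
binary floating point (all node values are dyadic rationals), which is
why the test suite can demand bit-for-bit equality with a
rational-arithmetic oracle.  Monte-Carlo acceptance bands are set at
roughly ±2–3 binomial standard errors of the replicate counts used.

## Known limitations

- D is defined here only for strictly bifurcating trees; polytomies are
  randomly resolved (distance-preserving), so D on heavily unresolved
  trees inherits a small resolution-seed dependence.
- The change-count convention (unweighted daughter means) is one of
  several in circulation; alternatives rescale consistently but are not
  implemented.
- Genus-level distances require ultrametric trees; there is no
  fallback to average cross-clade distances.
- The bioassay coupling in the generator is a rejection sampler; at
  extreme prevalence/floor combinations it will exhaust its retry
  budget and raise rather than silently relax the constraint.
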