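# Methods

This note records the models, conventions, and numerical choices behind
`morphoclad`, and what the synthetic-data tests do and do not demonstrate.

## Character model and scoring

Characters are unordered and multistate.  Each matrix cell carries an
*allowed state set*: a singleton for determinate cells, the observed set
for polymorphic cells, and the character's full state set for unknown
(`?`) and inapplicable (`-`) cells.  Unknown and inapplicable are kept
apart in I/O and summaries — fossil workers report them separately, and
their causes differ (non-preservation vs logical inapplicability) — but
parsimony scoring treats both as full ambiguity.  No reductive coding for
inapplicables is attempted; nothing in the pipeline requires one, and the
alternative (Maddison-style multiple-count corrections) would change step
counts in ways the rest of the workflow does not expect.  Polymorphic
cells are scored as ambiguity ("any one observed state suffices") rather
than as a requirement to reach every observed state; that matches the
behaviour of the standard parsimony programs this package mirrors.

Tree length is computed by a unit-cost Sankoff dynamic programme over
state sets (numba kernel; int64 costs; a large finite sentinel plays
infinity).  For binary trees this equals Fitch counting; for polytomies
it is exact for the *hard* reading (a multifurcation is a claim of
simultaneous divergence, not of uncertainty), which is what downstream
consensus-tree mapping needs.  Every tree-shaped quantity derives from
two cost arrays per node and character: `D[v][a]` (minimum steps inside
the subtree of `v` given state `a` at `v`) and `U[v][a]` (minimum steps
outside, given `a` at `v`'s parent).  From these come per-branch
minimum/maximum change counts over all most-parsimonious reconstructions
(MPRs), optimal state sets, and — with parallel counting arrays —
exact MPR-averaged branch changes.

Fit indices use the classical quantities per character: `m`, the minimum
steps over all trees, is one less than the size of the smallest state
set intersecting every cell's allowed set (found by brute force over
state subsets; state counts are small); `g` is the minimum steps on the
star tree; a character is parsimony-informative iff `g > m`.  Ensemble
CI and RI sum m, s, g over characters.  Whether uninformative characters
enter the sums is a flag (`include_uninformative`, default on): the
convention behind published ensemble values is often unstated, so both
are reported where it matters.

## Tree search

The heuristic reproduces "traditional search" semantics: taxa are added
in seeded-random order (over a canonical label-sorted base, so row order
is irrelevant), each at the insertion point of minimal length with ties
broken by the replicate RNG; the resulting tree is TBR-swapped, holding
up to `hold_per_replicate` equal-length trees, restarting whenever a
shorter tree appears; replicates are merged, filtered to the global
minimum, collapsed, and deduplicated by bipartition set — in that order.
TBR neighbourhoods are enumerated in deterministic canonical order
(bisect every edge; reattach every rerooting of one part to every edge
of the other), so a search is bit-reproducible from (matrix, config).
Scoring uses a branch-and-bound cutoff at the current acceptance
threshold.  The default desk profile is 50 replicates holding 20; the
published-style profile (1000 × 100) is a config away.

Zero-length-branch collapsing supports two readings, because published
"rules" are rarely defined precisely and the MPT count is sensitive to
them: `max_zero` (default) collapses a branch only when *no* MPR places
a change on it (maximum length zero); `min_zero` collapses when *some*
MPR does (minimum zero).  A degree-2 root is treated as an artefact: its
two incident edges are evaluated as the single unrooted edge they
represent.  Exhaustive enumeration (stepwise insertion with
branch-and-bound, refused above 9 taxa) provides exact minima, complete
MPT sets, and — with a retention slack — complete near-optimal tree sets
for validating the heuristics.

## Consensus and support

Bipartitions are canonicalised as the taxon set on the side away from a
reference taxon (the outgroup where given, else the smallest label), so
rooted and unrooted comparisons agree.  Strict consensus is a literal
set intersection; majority rule keeps splits in strictly more than the
cutoff fraction (cutoff < 50 % refused — compatibility is otherwise not
guaranteed).

Bootstrap pseudoreplicates resample characters with replacement and run
a reduced search (default 3 replicates holding 5; a knob).  Support is
the percentage of pseudoreplicates whose strict consensus contains the
split.  The reduced profile trades a ~1-point upward calibration bias
(measured against the analytic one-informative-character expectation of
65.1 %) for a ×3 runtime saving over a 10-replicate profile.

Bremer values come from one suboptimal-retention sweep: collect all
trees within `max_k` steps of the minimum (exhaustively below 10 taxa,
by slack-accepting TBR otherwise), then report, per split of the MPT
strict consensus, the smallest k at which it leaves the strict consensus
of the retained set; survivors are reported as `max_k`, to be read
"≥ max_k".  The sweep equals per-branch enumeration values on every
small matrix tested.

## Character mapping and grade-segment rates

Reconstruction policies: ACCTRAN and DELTRAN are implemented as preorder
backtraces of the Sankoff tables (at a tie between "change here" and
"change deeper", ACCTRAN changes on the current branch, DELTRAN defers;
remaining ties break to the smallest state index), and `mpr_average`
assigns each branch its exact mean change count over all MPRs
(fractional).  All three attain the Fitch length per character.

The segment-rate statistic answers "how labile is character category X
within taxon group Y" for groups that may be paraphyletic grades.  A
branch belongs to a group iff at least one group-assigned leaf descends
from it and all group-assigned descendants agree; spine branches whose
descendants span groups — and branches leading only to unassigned taxa,
including the outgroup — count for nobody.  This is the only assignment
that never double-counts a change between grades; the consequence,
asserted at runtime, is that grouped changes can sum to less than a
character's total transitions.  The rate divides grouped changes by the
number of the group's taxa with a determinate or polymorphic cell for
that character (the "scorable" count); groups with no scorable taxon are
excluded from category means.  Category means/SDs use the sample SD
(ddof = 1) over the characters of a category.  The default mapping tree
is the strict consensus with hard polytomies; mapping on each MPT and
averaging is available by passing the tree set.

## Disparity

With all-categorical characters and pairwise deletion, the Gower
distance is exactly the mismatch proportion over mutually scored
characters; polymorphic cells must be recoded to unknown first (the
recode step is explicit, and `gower_distance` refuses un-recoded
matrices rather than silently inventing states).  A pair with no shared
scored character aborts with the pair named — imputation would be
invisible and wrong.  Triangle-inequality violations are possible under
pairwise deletion; they are warned about, never fatal.

PCoA is classical metric scaling: double-centre −D²/2, eigendecompose
(symmetrised, `numpy.linalg.eigh`), coordinates = eigenvectors scaled by
√λ for eigenvalues above a relative 1e-12 tolerance.  No Lingoes/Cailliez
correction is applied; negative eigenvalues are reported, and axis
percentages are given against both the positive-eigenvalue sum (default)
and the absolute-value sum, since published "percent variance" figures
rarely say which convention they used.  The heatmap export emits 1 − d
with rows ordered base-to-apex: the left-to-right leaf sequence of the
ladderised (smallest-subtree-first, hence outgroup-first) consensus.

## Time-scaling and record gaps

Node ages use "basic" a-priori dating: each internal node is as old as
the oldest first-appearance datum (FAD) below it.  Zero-duration
*internal* branches are then stretched root-ward by ε (default 0.5 Myr,
purely presentational); terminal branches may legitimately have zero
duration since a leaf sits at its own FAD.  Gap finding is exact
interval arithmetic on [LAD, FAD] ranges — a sorted sweep over the
complement within the observed window, with a resolution threshold to
suppress sub-Myr slivers — validated against a 0.1-Myr grid scan.  A
bundled ICS stage table (Lochkovian–Changhsingian) converts stage names
to Ma for users whose range data are stage-resolved.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with defaults matching a study-scale fossil-seed matrix: 79 taxa; 89
characters in five category blocks (25/8/18/20/18: architecture, wall
structure, external topography, cellular, pollination-related); state
counts on {2..5} with mean 2.45 (≈ 218 states in total); per-character
rates Gamma-distributed (shape 2, mean 2 expected changes per character)
over a Yule tree whose total branch length is normalised to 1; 13.9 %
unknown, 10.5 % inapplicable, 0.1 % polymorphic cells.  Half of the
inapplicable cells (configurable) are placed hierarchically: a random
controlling character/state pair switches a block of 2–5 dependent
characters off for the affected taxa, emulating e.g. cupule characters
of acupulate taxa; the remainder, and all unknowns, are uniform.
Polymorphism is modelled as observational ambiguity — one extra recorded
state — not as biological polymorphism.  Character evolution is a
symmetric k-state Markov jump process (every jump changes the state and
is recorded on its branch), with no rate variation across branches:
recovery tests need known truth, not realism beyond the model the
analysis itself assumes.

Two deliberate profiles serve the validation suite:

* **strong_signal** (recovery tests): 20 taxa, 400 four-state
  characters, equal branch lengths, one expected change per character —
  about ten expected synapomorphies per branch.  Four states matter:
  with binary characters, parallel changes necessarily converge on the
  same state and occasionally produce *exactly* tied rival topologies
  (observed during development as one-polytomy consensus trees); with
  four states such convergence is rare and the generating tree is
  essentially always the unique optimum.
* **low-homoplasy rates** (rate-recovery tests): the same profile at 0.15
  expected changes per character.  Parsimony reconstruction counts
  systematically *undercount* realized changes once multiple hits are
  common (measured ≈ 3 % relative at one change per character), so
  unbiasedness of the segment-rate estimator is a low-rate statement and
  is tested as one.

What passing these tests shows: the machinery — scoring, search,
consensus, mapping, denominators, ordination algebra — is correct under
the generating model.  What they do not show: robustness to correlated
characters, branch-rate variation, ordered characters, or non-random
missingness beyond the hierarchical-inapplicable mechanism; real fossil
matrices violate all of these to unknown degrees.

## Problem sizes and numerical choices

The test suite runs everything at the scale of the statistical claim:
oracle equivalences on ≤ 8–9 taxa (where exhaustive enumeration is
exact), calibration at 1000 bootstrap pseudoreplicates, recovery over 50
simulations, rate unbiasedness pooled over 100.  The acceptance script
uses 20 recovery seeds and a 100-pseudoreplicate bootstrap for its
summary numbers.  Costs are int64 throughout the DP (no floating-point
ties); MPR counting uses float64 products, which is ample for the tree
sizes involved; seeds everywhere derive from a single user seed (per
stage via CRC32, kept below 2³¹).

## Known limitations

Ordered/additive characters, step matrices, and implied weighting are
out of scope (the target workflow uses none).  Likelihood and Bayesian
scoring are deliberately absent.  Bremer values above the sweep's
`max_k` are censored at `max_k`.  The heuristic search offers no
ratchet/sectorial acceleration, so very large matrices need the full
replicate budget and patience.  Reproduction of published
study statistics requires the study's own distributed matrix; the four
tests that assert those numbers fail with an explanatory message until
it is supplied (see README).
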