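# Methods

## Scope and data model

`spacerphy` analyzes CRISPR arrays as ordered sequences of spacer
identifiers. Arrays are stored leader-first throughout: index 0 is the
leader end, where new spacers are acquired, and the last index is the
trailer end, the evolutionarily older end subject to decay. Spacer
identity is nominal — two spacers are the same character if and only if
they carry the same identifier — with an optional preprocessing step
(`collapse_spacers`) that merges identifiers whose sequences differ by at
most a user-chosen number of bases. Array discovery itself (repeat
detection in assemblies) is out of scope; arrays enter through a plain
TSV, and spacer/repeat/genome sequences through FASTA.

## Spacer collapsing and orientation

Collapsing groups spacers by single linkage over pairwise base
differences: Hamming distance for equal-length sequences, unit-cost edit
distance (edlib) otherwise. Single linkage was chosen over centroid
clustering because it is order-independent and reproduces the intuitive
"chain of near-duplicates" behavior; the trade-off — long chains can
bridge dissimilar endpoints — is acceptable at the small thresholds
(≤ 2 bases) used in practice. A group's representative is the identifier
of its most frequent sequence, ties broken lexicographically, so the
mapping is deterministic.

Array orientation compares the summed distance of an array's repeats to
a user-supplied reference repeat against the distance to its reverse
complement; the better-fitting orientation wins, reversing spacer order
and reverse-complementing each spacer when needed. Exact ties keep the
input orientation and warn, making orientation an involution.

## Homology network

Two arrays sharing at least `min_shared` distinct spacers (default 2 —
a single shared spacer is weaker evidence and produces hairball graphs)
are connected by an edge weighted with the Jaccard similarity of their
unique-spacer sets. Clusters are connected components, numbered by
decreasing size with ties broken by smallest member id. Isolated arrays
are emitted in the node table so viewers show arrays without homologs.

## Comparison plots

Row order maximizes the number of spacers shared between adjacently
plotted arrays. Up to nine arrays all `n!` orders are scored (each order
ties with its reverse); beyond that a seeded stochastic search (20
random restarts, pairwise-swap hill climbing) is used, since the scoring
problem is a traveling-salesman-type objective with no cheap exact
algorithm. Spacers present in two or more plotted arrays receive
distinct (fill, outline) combinations drawn fill-major from an 8-color
colorblind-safe palette (Wong's set), assigned in order of first
appearance; combinations cycle with a warning once the k² space is
exhausted. Spacers unique to one array are drawn as thin black
rectangles, and identical spacers in adjacent rows are joined by lines.

## Pairwise engine

**Alignment.** Arrays are aligned with Needleman–Wunsch treating each
spacer as a character (match 100, mismatch −1, gap −2). The match score
dwarfs the penalties, so every shared spacer that order permits occupies
a match column in the optimum. Traceback ties are broken diagonal-first,
then gap-in-second, then gap-in-first, for reproducibility.

**Modules.** Alignment columns are classified (match → shared; both
present but different → mismatch; gap runs by position: touching the
leader column → leader acquisition in the ungapped array, touching the
trailer column → trailer indel, otherwise internal indel) and grouped
into maximal single-relationship runs. An indel run whose spacers all
have another copy in a shared column of the same array is a duplication
module.

**Ancestor inference.** The hypothetical ancestor is assembled module by
module: shared spacers are ancestral; leader-acquisition modules are
child-specific gains and excluded; internal and trailer indel spacers
are kept (one deletion, cost 10, or per-spacer trailer losses in the
sibling are cheaper than an insertion, cost 30, in the owner);
duplication modules reduce to the single ancestral copy. Mismatch
modules — mutually exclusive spacers aligned against each other — have
no locally forced fate: excluding both sides near the leader is cheap
(each child acquired its own spacers), while keeping one side is cheaper
internally (the other child carries a single replacement insertion, the
interpretation used for mid-array replacements in the tree plots). The
engine therefore scores every combination of exclude / keep-side-a /
keep-side-b across the mismatch modules, plus include/exclude fates for
indel modules when a mismatch is present (excluding an indel adjacent to
an excluded mismatch can merge two events into one) and the empty
ancestor, by the actual summed event cost of both children. Spacers that
would be gained on *both* branches are surcharged at the
independent-acquisition cost during this evaluation: independent gains
of identical spacers are the least plausible event in the model, so a
shared spacer is never dropped from an ancestor merely to shave event
costs. Ties prefer exclusion, then side a.

On instances the evolutionary model can generate — no rearrangement, so
shared spacers appear in the same relative order in both arrays — this
construction attains the exhaustive minimum over all gap-free ancestors
assembled from the alignment columns (property-tested on small random
instances). Arrays containing *transposed* shared spacers or repeated
spacers can admit cheaper ancestors that exploit alternative pairings of
duplicate copies; a single-alignment module method cannot represent
these, and since gain/loss evolution never reorders spacers, such inputs
indicate either rearrangement or identifier collisions upstream.

**Event annotation.** A descendant is aligned to its (gap-free) ancestor
and modules map to events: leader gains → one acquisition per spacer;
ancestral spacers missing at the trailer → one trailer loss per spacer;
missing internal (or leader-end) runs → one deletion per contiguous run;
descendant-only internal runs → one insertion per run; extra copies of
ancestral spacers → one duplication per copy; a mismatch run at the
leader → acquisitions plus one deletion, internally → one replacement
insertion. Cost is zero exactly when descendant equals ancestor.

## Tree inference

Trees are built by sequential addition: the first two arrays and their
inferred ancestor initialize the tree; each remaining array is compared
by alignment score with every node already present (leaves and
ancestors), attached as the sibling of its best match (ties: node
closest to the root, then name order), and ancestors along the root path
are regenerated. All `n!` addition orders are tried for up to six
arrays, otherwise 100 seeded random orders — enough for the search to be
stable on the instance sizes the tool targets while keeping a single
inference in seconds. Pairwise results are memoized across orders, which
is what makes the search cheap: the same ancestors recur constantly.

Each finished tree is scored by total branch cost; internal nodes whose
branch cost is zero (their array equals their parent's) are collapsed
into polytomies, which preserves the total. The cheapest tree(s) are
returned, deduplicated by their node encodings; every constructed tree
counts once in the support denominator. Internal nodes are named
`Anc_a`, `Anc_b`, … in discovery order. Newick output carries branch
lengths equal to branch costs and, optionally, support appended to the
internal label.

For small instances `exhaustive_best_cost` enumerates all (2n−3)!!
rooted binary topologies and fills each post-order with the same
ancestor inference; the sequential-addition search is validated against
it (≥ 90% of random 3–5-array instances reach the exhaustive minimum;
the heuristic can never beat it since its trees lie in the enumerated
space).

## Fixed-topology reconstruction and independent acquisitions

`constrain` populates a user-supplied Newick topology post-order with
the same ancestor inference; polytomies are resolved by greedily pairing
the two most similar children (by alignment score). Each branch is then
annotated with events. Spacers appearing in acquisition or insertion
events on two or more branches are flagged as independent acquisitions
— the signature of horizontal transfer or convergent acquisition when a
forced topology separates arrays that share recently acquired spacers.
Contiguous flagged spacers on one branch form a single run. By default
flags only highlight; with `recost=True` each flagged run replaces its
original gain cost with the independent-acquisition cost (50) and branch
costs update. Highlight-only is the default so that constraining to the
topology the free search produced reproduces its total cost exactly.

## Simulator

The simulator starts from a founder of `initial_length` (default 5)
novel spacers. At each of `n_events` steps one extant lineage is chosen
uniformly and spawns a child: a copy to which one sampled event is
applied — acquisition of a globally unique spacer at the leader,
deletion of a contiguous run (uniform start, geometric length with mean
2, truncated so arrays keep at least one spacer; single-spacer arrays
substitute an acquisition), loss of the trailer-most spacer, or in-place
duplication of a uniformly chosen spacer. Event-type probabilities are
parameters (the remainder after acquisition/deletion/trailer-loss is
duplication); with probability `array_loss_rate` the parent lineage is
marked lost after spawning. The true tree records every spawn: a
lineage's node has its spawned children as subtrees plus, if the lineage
survived, a leaf carrying its own array; lost childless lineages vanish
and unifurcations are suppressed. A lineage's array is fixed at birth
(events apply to the child copy), so repeated spawns from one lineage
form a polytomy — the honest representation, since nothing orders them.

These update rules are this package's own specification of an
array-evolution process; they emulate leader-biased gain and
deletion-biased loss with known ground truth, but not repeat mutation,
ectopic acquisition, selection, or recombination between arrays. Tests
passing on simulated data therefore demonstrate correct reconstruction
*under the model's assumptions*, not performance on arrays shaped by
processes the simulator omits.

## Tree comparison and benchmark

Robinson–Foulds distance is computed unrooted: the symmetric difference
of non-trivial bipartitions, normalized by the total number of
non-trivial bipartitions across both trees (0/0 is defined as 0 for two
star trees). The benchmark grid runs seeded replicate simulations per
(deletion share, event count) cell, infers a tree from the extant
arrays, and reports the proportion of exact recoveries (normalized RF
= 0) and the median normalized RF. Default study conditions: 50
replicates per cell; 20 events for the acquisition-only check; 12 events
for the deletion gradient {0, 0.25, 0.5}, sizes at which a full grid
runs in minutes on one CPU. Recovery is perfect without deletions and
degrades as deletions erase the shared-suffix signal, and is robust to
cost perturbations that preserve acquisition < deletion < independent
acquisition.

## Protospacer search

The internal search is seed-and-extend: exact k-mer seeds (k = 8,
shortened to ⌊L/(m+1)⌋ when m allowed mismatches demand it, so the
pigeonhole principle guarantees one clean seed per true hit, including
hits hanging off a contig end) locate candidates, which are extended to
the full spacer length; mismatches are counted over the full length with
off-contig positions counting as mismatches. Both strands are searched.
Hits below the identity threshold, or overlapping a masked interval by
at least one base, are dropped. The PAM is read from the flank
immediately adjacent to the protospacer *on the protospacer's strand*
(default `CC` on the 5′ side, the type I–F motif) and matched as an
IUPAC pattern; hits whose flank runs off the contig get an undetermined
PAM status rather than a pass or fail. Target summaries count distinct
subject sequences per spacer and can be emitted as a color scheme for
the comparison and fixed-topology plots.

## Numerical and degenerate-input choices

Costs are floats with exact small-integer defaults, so equality
comparisons on totals use a 1e-9 tolerance. Empty ancestors (no
inherited material) are representable inside the tree machinery; a
branch from an empty ancestor charges one acquisition per descendant
spacer. Deletions never empty a simulated array. All stochastic
components (tree search orders, plot-order restarts, simulations) take
explicit seeds and are reproducible bit-for-bit under them.

## Known limitations

- Spacer comparison is nominal after collapsing; sequence-level
  similarity beyond the collapse threshold is invisible downstream.
- Ancestor inference is single-alignment and module-based; arrays with
  transposed shared spacers (impossible under pure gain/loss) may admit
  cheaper histories it cannot represent.
- The sequential-addition search is heuristic beyond six arrays; the
  100-order default can miss the global optimum on adversarial
  instances (tracked at ≥ 90% optimality on small random instances).
- Support values measure search-replicate agreement, not statistical
  confidence.
- The protospacer scan is exact-identity-oriented (mismatch thresholds,
  no gaps); it is not a local aligner and reports no E-values.
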