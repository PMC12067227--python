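# Methods

This note documents the models, algorithms and design choices behind
`phylosynth`, in the spirit of a statistical-software methods appendix:
what each stage assumes, which knobs matter, and what the synthetic
fixtures do and do not demonstrate about real data.

## Rooted semantics

All trees are rooted, and the unit of topological information throughout
is the **cluster**: the set of tips descending from a rooted edge. The
Robinson–Foulds distance is accordingly the symmetric difference of
rooted cluster sets (the root cluster and single-tip clusters excluded),
not the unrooted bipartition count; the two differ and the rooted variant
is the one that matches the synthesis algorithm's semantics. Polytomies
are treated as soft — an absence of resolution, never an assertion of
simultaneous divergence.

## Synthesis

### Exemplification

Input tips are mapped to species-rank units by walking up the taxonomy;
tips below species rank collapse onto their species, and when several tips
land on one species a single exemplar is kept. The exemplar is the tip
with the lexicographically smallest original label — an arbitrary but
deterministic rule; since duplicate tips of one species carry no
between-species information, the choice cannot affect accepted clusters,
only tie-breaking reproducibility. A tree reduced below two tips is
rejected as uninformative. The same collapse rule handles lumped concepts
in cross-version label translation, so the two operations agree by
construction.

### Uncontested decomposition

A named taxon is *contested* when its species set, restricted to the tips
shared with some input tree, overlaps one of that tree's clusters with
neither containing the other. Uncontested taxa are monophyletic in every
possible synthesis consistent with the inputs, so they decompose the
problem: every uncontested named taxon (with ≥ 2 species) becomes a
subproblem, nested subproblems are collapsed to a single representative
species in their parent, and an artificial root subproblem covers the
top-level structure. The decomposition is recursive rather than single
level: with no conflicting input at all, the working subproblems are the
smallest non-trivial named groups, which keeps each greedy run small.
Contested taxa are dissolved structurally but their clusters remain in
play as taxonomy evidence.

### Greedy assembly and BUILD

Within a subproblem, cluster constraints are processed in rank order —
tree by tree, and root-to-tip (largest clusters first, lexicographic
tie-break) within a tree; the within-tree order is a design choice (deeper
edges constrain more) since any cluster order within one tree is
self-consistent. Taxonomy clusters always come last. A cluster C from a
source with tip set L is the constraint "C is a clade relative to L \ C",
i.e. the rooted triplets ab|c for a, b ∈ C, c ∈ L \ C. A candidate is
accepted iff the accepted set plus the candidate remains jointly
satisfiable, decided by the Aho BUILD algorithm run over the constraints
(union the members of each active constraint at every recursion level;
fail on a connected level with live constraints). BUILD also produces the
output tree: the minimally resolved tree displaying exactly the accepted
constraints, so unforced regions stay polytomies.

Two consequences are guaranteed and asserted in tests: every cluster of
the top-ranked tree is displayed, and taxonomy clusters can never displace
input-supported ones (taxonomy is considered last and acceptance is
monotone). Determinism is byte-level: children are canonically ordered by
smallest descendant label before serialization.

### Annotations

Each accepted constraint annotates the smallest output edge realising it
(`supported_by`); a rejected cluster is recorded as `conflicts_with` on
the highest-ranked accepted edge whose prefix first became unsatisfiable
with it — a deliberate single-blame rule at synthesis time, with the full
edge-by-tree classification recomputed post hoc by the conflict module.
Edges supported only by the taxonomy carry a `terminal` flag, as do tips
of species absent from every input. The phylogeny-only variant of the
output prunes taxonomy-only tips and contracts taxonomy-only internal
edges, so that every internal edge of that tree is supported by at least
one input phylogeny, by construction.

## Conflict classification and alignment

The alignment rule: restrict the synthesis and a source tree to their
shared tips, suppressing unary nodes; node X aligns to node Y when their
descendant species sets are equal, and the relation is upgraded to
*supported* when X's parent survived the restriction. The induced root is
treated as parent-retained vacuously — this is what allows published
root-age estimates to map onto the synthesis root for dating. Edge
classification against one source yields exactly one of *supports*
(exact cluster match at the retained representative), *conflicts*
(overlap, neither containing the other), *compatible* (nested or
disjoint throughout, or an exact match whose parent was suppressed), or
*uninformative* (fewer than two shared tips below the edge, or none
outside it). Because the restricted clusters of a single source tree form
a laminar family, an edge can never receive both supports and conflicts
from the same source.

## Taxon addition (grafting)

An addition statement gives a missing species, an ordered anchor list
(most specific last; a named taxon or the MRCA of listed species) and
exclusion clades whose monophyly must not be broken. Placement uses the
most specific anchor resolvable in the current tree: candidate edges are
those strictly within the anchor clade — the anchor's own stem is not
"within" it — minus the interiors of exclusion clades, whose stems remain
legal so sister-to placements stay possible. Two boundary rules make
sparse sampling work:

- an anchor resolving to a single tip has that tip's stem as its one
  candidate (the sister-to-the-only-member placement);
- when every in-anchor edge is excluded *and* the anchor is undersampled
  (its MRCA in the tree spans fewer species than the taxonomy assigns to
  it), the anchor's stem becomes the candidate — sister to the sampled
  part is still inside the true clade. A fully sampled anchor whose
  interior is entirely excluded is genuinely over-constrained and errors.

Statements are shuffled with the seeded generator, then stably reordered
so that statements referencing other missing taxa follow their referents
(a sister-to-a-missing-species anchor is unresolvable before the referent
exists). Attachment subdivides a uniformly drawn candidate edge with a new
bifurcation; uniform edge choice is pinned (the chooser is a seam —
branch-length- or diversification-weighted choices are out of scope since
the synthesis tree carries no branch lengths). Sampling n completions
derives per-tree sub-seeds from one master seed (NumPy PCG64, pinned for
cross-platform reproducibility) and re-verifies every statement on every
tree post hoc, aborting on any violation.

## Dating

### Age collection and calibration draws

Ages flow from dated sources to the synthesis through the *supported*
alignment pairs only; when topologies disagree, the conflicting source
nodes simply contribute nothing. Each node's evidence reduces to one
calibration in either of two modes. *Mean*: the per-node arithmetic mean.
*Sample*: a uniform draw among the node's records, with a node holding
exactly one record included with probability 1/2 — sampling or excluding a
lone estimate with equal odds, so that a single study cannot silently pin
a node. The root is exempt from the coin flip: a root calibration is
required (an error otherwise) and is drawn uniformly from the root's
records. A root-to-tip sweep enforces strict monotonicity: a drawn age at
or above the nearest retained ancestor's age triggers a redraw restricted
to the valid records, or exclusion of the node when none remain (in mean
mode, exclusion directly — there is nothing to redraw). Exclusion of
single-record nodes happens before the sweep. Source credible intervals
are deliberately not consumed.

### bladj even spacing

Calibrated ages are fixed exactly. Uncalibrated nodes are assigned top
down, so previously assigned ages anchor their descendants (matching the
behaviour of the original even-spacing implementation): a node one step
below its (already aged) ancestor of age *a*, with *k*+1 node-steps down
to its nearest calibrated-or-terminal descendant of age *d*, receives
*a* − (*a* − *d*)/(*k*+1). The nearest descendant anchor is chosen by
minimum node-steps, ties going to the older age. One refinement is needed
for correctness: deeper *calibrated* anchors act as even-spacing floors —
without this, a shallow tip next to a deeper, older calibration could
force a negative branch. With the floor rule all branch lengths are
strictly positive and trees of extant tips are exactly ultrametric
(asserted to 1e-9 Myr). On a chain calibrated only at its ends the rule
reproduces the arithmetic progression in closed form.

Dating a completion cloud aligns the dated sources once against the
shared phylogenetic core (grafted taxa never carry dates), transfers each
record to the corresponding MRCA in every completion, and runs a fresh
calibration draw (derived sub-seed) plus bladj per tree.

## Cloud summaries

The MCC tree is the cloud member maximizing the sum of log clade
frequencies (ties to cloud order); the majority-rule consensus assembles
all clusters occurring in more than half the trees, which are pairwise
compatible by pigeonhole (asserted anyway). In both summaries node ages
are the mean age of the clade over the trees containing it, with a child
mean at or above its parent clamped to parent − 1e-6 Myr so branch lengths
stay positive, and 2.5–97.5 percentile intervals report the spread.
Percentile intervals were chosen over HPD deliberately: deterministic,
simple, and adequate for interval reporting on node dates; the choice is a
seam, not a commitment. The root cluster is included in the clade table
(frequency 1) so root ages are summarized like any other node's.

## Phylogenetic diversity

Patristic distance is the branch-length path sum through the MRCA;
assemblage MPD is the unweighted mean over unordered pairs,
presence/absence only (abundance weighting and the spatial gridding of
raw occurrence records are upstream of this package). Singleton
assemblages yield a missing value, never zero — an undefined mean is not
a small one.

## Synthetic fixtures: what they emulate, and what they don't

The generator produces a dated pure-birth (Yule) tree — uniform lineage
choice, exponential waits, rescaled to a configurable root age, 100 Mya
by default to match an avian-scale crown — with tip labels assigned in
random order so small labelled topologies are exchangeable. The taxonomy
is built by cutting the true tree at two ages (defaults: genera at 25%,
families at 60% of the root age), so named groups are true clades and
monophyly holds by construction. Input trees are induced subtrees of the
truth; conflict is injected by a single rooted NNI, the smallest
perturbation that guarantees a conflicting cluster; dated variants carry
the true node ages, optionally with symmetric multiplicative noise
truncated to preserve parent-older-than-child. Addition statements anchor
held-out species at their true genus (family fallback) and exclude every
sibling genus, so the true placement is always among the candidates.
Assemblages are drawn uniformly or from within a random clade, mimicking
overdispersed versus phylogenetically clustered communities.

Passing tests on these fixtures demonstrates algorithmic correctness —
exact recovery under full, conflict-free coverage; the greedy ranking
guarantee; constraint satisfaction of every sampled completion; exact
mean-mode age recovery — but not robustness to the pathologies of real
curated corpora: mis-rooted inputs, taxonomic misidentification,
correlated conflict among studies sharing data, non-Yule tree shape, or
fossil tips. Corpus-scale statistics reported for real datasets (hundreds
of input trees, thousands of conflicting branches) depend on the real
inputs and are out of scope here.

## Numerical and scale choices

Test-suite and acceptance runs use desk-scale problems (tens of species,
single-digit tree counts, clouds of 20–100, 2,000-draw Monte Carlo
checks); the algorithms are quadratic-ish in tips at worst and these sizes
keep the whole suite in seconds on one CPU. Default fixture conditions —
100-tree completion clouds, equal-probability single-date sampling,
uniform candidate-edge choice — are the study conditions, not tuning
knobs. Other fixed constants: positivity clamp ε = 1e-6 Myr,
ultrametricity tolerance 1e-9 Myr, percent reporting rounded half-up to
integers (checklist-table convention).

## Known limitations

- The greedy-time conflict annotation blames a single blocking edge;
  full conflict structure requires the post-hoc classifier.
- Majority-rule consensus ages reuse common-ancestor clade means; nodes
  absent from most trees are simply absent, not interpolated.
- `read_age_records` re-attaches records via two-tip MRCA fingerprints
  and assumes the target tree displays the fingerprinted clades.
- No birth–death gap-filling for undated nodes and no rate-smoothing
  (penalized likelihood) alternative to even spacing.
- Unrooted inputs are rejected rather than rooted heuristically.
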