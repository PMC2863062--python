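# Methods

## The model

`treeify` converts a weighted undirected network — typically a protein
interactome whose edge weights estimate interaction reliability or
functional linkage, scaled into [0, 1] — into a hub-oriented tree, and
reads functional modules off that tree.

**Path strength.** For a simple path p = ⟨v₀, …, vₙ⟩ the strength is

    S(p) = λ · ∏ᵢ w_{i,i+1} / ∏_{interior vᵢ} d_wt(vᵢ)

the product over the path's edge weights divided by the weighted degrees
d_wt (sum of incident edge weights) of the *interior* nodes.  Each factor
w / d_wt is the weighted probability that a node hands the signal to that
particular neighbor; exempting the two endpoints from the degree divisor
makes S invariant under path reversal, which is what lets it induce a
symmetric similarity.  λ is a global scale, default 1.  Every factor is
≤ 1, so strength is non-increasing as a path grows — the property that
powers both the length bound and the exact branch-and-bound pruning.

**Functional similarity.** F(a, b) is the maximum strength over simple
paths between a and b of length l to l + θ, where l is the unweighted
(hop) shortest-path distance and θ (default 2) caps the detour length.
The default reflects the small-world character of interactomes: mean
similarity collapses toward 0 beyond three hops (the test suite verifies
this decay on synthetic networks), so longer detours change nothing but
cost exponentially more search.  Disconnected pairs have F = 0;
self-similarity is undefined and never used.

**Tree conversion.** Centrality C(a) = Σ_{b≠a} F(a, b).  Nodes are
totally ordered by centrality descending (node id ascending breaks
exact ties, keeping the construction deterministic even on degenerate
inputs); each node's parent is the node it is most similar to among the
nodes preceding it in that order within its connected component, and the
per-component maximum becomes that component's root.  Because parents
strictly precede children in a total order, the result is always a
forest with one tree per component.

**Hubs and modules.** Hub confidence
H(a) = Σ_{x ∈ descendants(a)} F(a, x) / F(a, parent(a)), with H = 0 for
leaves and H = C(a) for roots — the ratio of how strongly a node binds
the subtree below it to how strongly it is bound upward.  Clusters are
emitted in descending-H order as {a} ∪ descendants(a) until the first
node drops below a user threshold; as subtrees of one tree they form a
laminar (nested-or-disjoint) family.  A cluster's depth is the longest
downward path from any member to a leaf; smaller depth ≈ more specific
module.  The package default threshold is H ≥ 1 — the hub binds its
subtree at least as strongly as its parent — since the measure's natural
unit is the parent similarity; on the synthetic benchmark, recovery is
insensitive to this choice between 0 and 1.

## Search strategy and numerics

All-pairs similarity runs one depth-limited DFS over simple paths per
source node, visiting each unordered pair from its lexicographically
smaller endpoint so stored values are symmetric *by construction* (the
two directions of the same float products can differ in the last ulp;
fixing the direction removes the ambiguity).  A prefix whose strength
falls to or below `prune_epsilon` (default 1e−9) is abandoned — exact
pruning, since extensions only shrink strength; setting it to 0 restores
exhaustive enumeration, and the test suite checks bit-for-bit agreement
with an independent oracle that enumerates every simple path via
networkx on graphs of ≤ 12 nodes.  A per-source expansion budget guards
against pathological dense inputs; exceeding it raises an error that
suggests a larger `prune_epsilon` rather than silently truncating.
Multiplication order in the DFS mirrors the standalone `path_strength`
function exactly, so the two routes agree without tolerance.

Degenerate inputs: duplicate edges keep the maximum weight (conservative
merge of repeated evidence); self-loops are dropped with a warning;
weights outside [0, 1] are rejected unless min–max normalization over
the input file is requested; equal-centrality ties fall back to node-id
order everywhere a total order is needed.

## Edge weighting

For unweighted networks two weighting schemes are built in.  The
hypergeometric scheme scores each edge (vᵢ, vⱼ) by the upper-tail
probability P of drawing at least s = |N(vᵢ) ∩ N(vⱼ)| shared neighbors
by chance (population |V|, marked |N(vᵢ)|, drawn |N(vⱼ)|, endpoints
removed from both neighbor sets first — their trivial co-occurrence is
not evidence); the weight is 1 − P.  The co-expression scheme maps the
Pearson correlation r of the endpoints' expression profiles to
(r + 1)/2, preserving order over the whole correlation range instead of
clamping negative r to 0; constant profiles get the neutral 0.5.  Any
weighting can be audited by the cumulative functional-consistency curve:
edges ranked by weight, Jaccard index of the endpoints' annotation term
sets accumulated along the ranking.  Pairs where neither endpoint is
annotated are undefined — excluded from the curve, never counted as 0.
Semantic-similarity weighting over an ontology is out of scope; the tool
accepts externally pre-computed weights instead.

## Evaluation battery

* **Attack curves** remove nodes one at a time (uniform random with a
  seed; highest current degree, recomputed per step; or descending hub
  confidence, ranked once on the intact network by default since
  re-ranking costs a full similarity recomputation per step — a
  `recompute` flag enables it) and record the largest-component fraction
  relative to the original node count.
* **Normalized modularity** of a node set S is m / p with
  m = E_in / E_inc (edges inside S over edges touching S, each edge
  counted once) and p = (|S| − 1)/(|V| − 1), the probability that a
  uniformly chosen potential partner of a member lies inside S.  p is
  recorded in every score so results remain interpretable under other
  normalizations.
* **Cluster accuracy** is the mean, over reference modules, of the best
  f-measure (harmonic mean of precision and recall) any cluster achieves
  against that module, reported per annotation level.
* **Ranked profiles** summarize a per-node property (lethality flags,
  term counts) along any ranking in consecutive windows (default 10
  nodes) and cumulatively, so degree- and confidence-based rankings are
  compared through one code path.

## The synthetic benchmark

The generator plants a two-level hierarchy: 3 modules × 2 sub-modules ×
6 nodes, plus per module one designated hub (wired to 80% of module
members and to the other hubs) and two peripheral degree-1 nodes hanging
off a single member each — the low-degree periphery real interactomes
always carry.  Sub-modules are near-cliques (edge probability 0.9,
weights U(0.7, 0.95)); cross-sub-module edges are sparser and weaker
(0.3, U(0.4, 0.6)); cross-module background is rare and weak
(0.04, U(0.05, 0.2)).  Annotations give every node its module term
(level 1) and sub-module term (level 2); hubs collect the terms of all
modules they touch, so term-overlap profiles peak at hubs by
construction.  Lethality is drawn at 0.8 for hubs and 0.1 elsewhere.
Expression profiles are a module latent factor plus a sub-module offset
plus N(0, 0.3²) node noise over 12 conditions, so co-expression
weighting recovers module structure.  All randomness flows through one
seeded generator; identical spec and seed give byte-identical fixtures.
A separate preferential-attachment generator supplies scale-free
topologies for the attack experiments.

What the fixture does *not* emulate: hierarchy deeper than two levels
(the generator is fixed at modules-of-sub-modules), inspection-biased
degree distributions, false-negative edges, or realistic annotation
incompleteness.  Consequently, passing recovery tests show the pipeline
retrieves planted two-level structure under favorable contrast, not that
it would score comparably on a real curated interactome.  One measured
consequence: below the sub-module scale the fixture has no real
structure, so depth-1 clusters are partly sub-module fragments and mean
normalized modularity is flat-to-slightly-increasing between depths 1
and 2 instead of strictly decreasing; from depth 2 upward the expected
monotone decay holds.

## Problem sizes

Default verification sizes are chosen for desk-scale reproducibility:
45-node planted fixtures (20 seeds) for recovery, leaf, and modularity
properties; 60-node scale-free networks (20 seeds, 10% removal) for
attack curves; ≤ 12-node random graphs (100 instances) for exact
oracle equivalence.  The full suite runs in about two minutes on one
CPU.
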