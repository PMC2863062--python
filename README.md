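# treeify

Convert a weighted protein–protein interaction network into a
hub-oriented hierarchy, score every protein's *hub confidence*, and
extract hierarchically nested functional modules.

Interactome networks are noisy, densely connected, and hard to read, but
they carry two strong signatures: modularity (functions live in densely
wired sub-graphs, recursively — modules contain more specific
sub-modules) and a hub-oriented topology.  `treeify` exploits both.  It
measures functional similarity between proteins with a *path-strength*
model, orders proteins by path-strength centrality into a tree, and
reads hubs and nested modules directly off that tree.  It is aimed at
anyone analyzing weighted biological networks who wants a global,
hierarchical view instead of a flat clustering: which proteins hold the
network together, and which subtrees behave like functional modules.

## The model in brief

For a simple path p = ⟨v₀, …, vₙ⟩ with edge weights w ∈ [0, 1]:

    S(p) = λ · ∏ᵢ wᵢ,ᵢ₊₁ / ∏ d^wt(vᵢ)        (interior nodes vᵢ only)

where d^wt(v) is the weighted degree of v.  Functional similarity is the
best route within a bounded detour:

    F(a, b) = max { S(p) : p simple a→b path, l ≤ |p| ≤ l + θ }

with l the shortest-path hop distance and θ = 2 by default.  Centrality
C(a) = Σ_b F(a, b) orders proteins; each protein attaches to the
most-similar protein above it in that order, producing a tree.  Hub
confidence H(a) is the summed similarity of a to its tree descendants
divided by its similarity to its parent (roots use C(a); leaves score
0).  Visiting nodes by descending H, each subtree {a} ∪ descendants(a)
with H ≥ a threshold is emitted as a module; modules nest, and each
carries a depth label (longest member-to-leaf path) — smaller depth,
more specific function.

For unweighted networks two weighting schemes are included: the
significance of an edge's shared neighborhood (1 − hypergeometric tail
probability) and expression-profile correlation ((r + 1)/2).  An
evaluation battery covers attack-vulnerability curves, size-normalized
modularity, best-match f-measure against reference modules, and ranked
lethality/term-overlap profiles.

## Worked example

The 4-node toy network `A–B 0.8, A–C 0.6, B–C 0.4, C–D 0.5`:

```sh
printf 'A\tB\t0.8\nA\tC\t0.6\nB\tC\t0.4\nC\tD\t0.5\n' > toy.tsv
treeify run --network toy.tsv --out-dir toy_out --h-threshold 0.5
```

prints `pipeline outputs in toy_out (2 clusters)` and writes
`fmatrix.tsv`, `tree.tsv`, `hubs.tsv`, `clusters.tsv` and a
`manifest.json` recording parameters and output checksums.

```
$ cat toy_out/tree.tsv
node    parent  centrality
A       -       1.6
C       A       1.5
B       A       1.333333333
D       C       0.8333333333
```

A is the most central protein (C(A) = F(A,B) + F(A,C) + F(A,D) =
0.8 + 0.6 + 0.2 = 1.6) and becomes the root; D's best route upward is
its direct edge to C (F = 0.5), so it attaches under C.

```
$ cat toy_out/hubs.tsv
node    hub_confidence  rank
A       1.6     1
C       0.8333333333    2
B       0       3
D       0       4
```

C's confidence is F(C,D)/F(C,A) = 0.5/0.6 = 0.83: it binds its subtree
(D) almost as strongly as it is bound to its parent.  B and D are
leaves, so their confidence is 0 — degree-1 proteins can never be
structural hubs.

```
$ cat toy_out/clusters.tsv
hub     depth   hub_confidence  members
A       2       1.6     A,B,C,D
C       1       0.8333333333    C,D
```

Two nested modules: the whole component under A (depth 2), and the more
specific pair {C, D} under C (depth 1).

Other entry points: `treeify weight` (hypergeometric / co-expression
edge weights), `treeify similarity`, `treeify build-tree` (optionally
Newick), `treeify evaluate vulnerability|modularity|fmeasure|profile`,
and `treeify make-fixture`, which writes a seeded synthetic benchmark —
a planted two-level module hierarchy with hubs, annotations, lethality
flags, and expression profiles.  See `docs/methods.md` for the model
details, parameter defaults, and the benchmark's construction.

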