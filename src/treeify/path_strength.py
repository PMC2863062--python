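"""The path-strength model of functional similarity.

The strength S(p) of a simple path p = <v0, ..., vn> in a weighted network
is the product of the weighted probabilities that each node chooses its
successor on p:

    S(p) = lambda * prod(w_i,i+1) / prod(d_wt(v_i) for interior v_i)

where w_i,i+1 is the weight of the i-th edge and d_wt(v) is the weighted
degree of v.  The endpoints contribute no degree divisor, which makes the
strength invariant under path reversal and hence the similarity symmetric.

The functional similarity F(a, b) is the maximum strength over all simple
paths between a and b whose length k (in edges) satisfies l <= k <= l + theta,
with l the unweighted shortest-path distance.  Because each extension of a
simple path multiplies its strength by a factor w / d_wt <= 1, strength is
non-increasing in prefix length, which both bounds F by lambda and makes
branch-and-bound pruning exact below any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx

from treeify.graph_io import ValidationError, WeightedNetwork


@dataclass(frozen=True)
class PathStrengthParams:
    """Tunable parameters of the path-strength search.

    theta
        Maximal extra path length beyond the shortest path (default 2:
        paths of length l, l+1 and l+2 are considered, since similarity
        is negligible beyond that in small-world interactomes).
    lambda_scale
        Global multiplicative scale of all strengths (default 1).
    prune_epsilon
        Branch-and-bound threshold: a partial path whose strength falls
        to or below this value is abandoned.  0 restores exhaustive
        enumeration.
    max_abs_depth
        Hard safety cap on search depth regardless of theta.
    max_expansions
        Budget on DFS node expansions per source; exceeding it aborts
        with a message suggesting a larger prune_epsilon.
    """

    theta: int = 2
    lambda_scale: float = 1.0
    prune_epsilon: float = 1e-9
    max_abs_depth: int = 12
    max_expansions: int = 50_000_000

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValidationError("theta must be >= 0")
        if self.lambda_scale <= 0:
            raise ValidationError("lambda_scale must be > 0")
        if self.prune_epsilon < 0:
            raise ValidationError("prune_epsilon must be >= 0")
        if self.max_abs_depth < 1:
            raise ValidationError("max_abs_depth must be >= 1")


class SearchBudgetExceeded(RuntimeError):
    """The DFS expansion budget was exhausted; raise prune_epsilon."""


@dataclass
class SimilarityStore:
    """Cached pairwise functional similarities F(a, b).

    Values are stored once per unordered pair; lookups are symmetric.
    Pairs in different components have F = 0 and may be absent from the
    backing dict.  ``shortest_lengths`` caches the hop distance l used for
    each stored pair.
    """

    values: dict[frozenset[str], float] = field(default_factory=dict)
    shortest_lengths: dict[frozenset[str], int] = field(default_factory=dict)

    def get(self, a: str, b: str) -> float:
        if a == b:
            raise ValidationError("self-similarity F(a, a) is undefined")
        return self.values.get(frozenset((a, b)), 0.0)

    def set(self, a: str, b: str, value: float, l: int | None = None) -> None:
        key = frozenset((a, b))
        self.values[key] = value
        if l is not None:
            self.shortest_lengths[key] = l

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        for key, v in self.values.items():
            a, b = sorted(key)
            yield a, b, v

    def __len__(self) -> int:
        return len(self.values)


def path_strength(
    path: Sequence[str],
    net: WeightedNetwork,
    params: PathStrengthParams = PathStrengthParams(),
) -> float:
    """Strength of a given simple path.

    Multiplications follow the path left to right (edge weight in, then
    the degree divisor of the node that just became interior), matching
    the incremental update of the DFS search bit for bit.
    """
    if len(path) < 2:
        raise ValidationError("a path needs at least one edge")
    if len(set(path)) != len(path):
        raise ValidationError(f"path {list(path)} repeats a node")
    s = params.lambda_scale
    for i in range(len(path) - 1):
        u, v = path[i], path[i + 1]
        if not net.has_edge(u, v):
            raise ValidationError(f"({u}, {v}) is not an edge of the network")
        s *= net.weight(u, v)
        if i > 0:
            s /= net.weighted_degree(u)
    return s


def _simple_paths_exact_length(
    net: WeightedNetwork, a: str, b: str, k: int
) -> Iterator[list[str]]:
    for p in nx.all_simple_paths(net.graph, a, b, cutoff=k):
        if len(p) - 1 == k:
            yield p


def k_length_strength(
    a: str,
    b: str,
    k: int,
    net: WeightedNetwork,
    params: PathStrengthParams = PathStrengthParams(),
) -> float:
    """Maximum strength over all simple paths of exactly k edges; 0 if none."""
    if a == b:
        raise ValidationError("endpoints must differ")
    if k < 1:
        raise ValidationError("k must be >= 1")
    best = 0.0
    for p in _simple_paths_exact_length(net, a, b, k):
        best = max(best, path_strength(p, net, params))
    return best


def _shortest_length(net: WeightedNetwork, a: str, b: str) -> int | None:
    try:
        return nx.shortest_path_length(net.graph, a, b)
    except nx.NetworkXNoPath:
        return None


def functional_similarity(
    a: str,
    b: str,
    net: WeightedNetwork,
    params: PathStrengthParams = PathStrengthParams(),
) -> float:
    """F(a, b): max k-length strength for l <= k <= l + theta; 0 if disconnected."""
    if a == b:
        raise ValidationError("self-similarity F(a, a) is undefined")
    l = _shortest_length(net, a, b)
    if l is None:
        return 0.0
    return max(
        k_length_strength(a, b, k, net, params) for k in range(l, l + params.theta + 1)
    )


def oracle_similarity(
    a: str,
    b: str,
    net: WeightedNetwork,
    params: PathStrengthParams = PathStrengthParams(),
) -> float:
    """F(a, b) by unpruned exhaustive enumeration; test oracle, |V| <= 15 only."""
    if net.n_nodes > 15:
        raise ValidationError(
            f"oracle refuses graphs above 15 nodes (got {net.n_nodes})"
        )
    if a == b:
        raise ValidationError("self-similarity F(a, a) is undefined")
    l = _shortest_length(net, a, b)
    if l is None:
        return 0.0
    src, dst = (a, b) if a <= b else (b, a)
    best = 0.0
    for p in nx.all_simple_paths(net.graph, src, dst, cutoff=l + params.theta):
        best = max(best, path_strength(p, net, params))
    return best


def all_pairs_similarity(
    net: WeightedNetwork,
    params: PathStrengthParams = PathStrengthParams(),
) -> SimilarityStore:
    """F for every unordered pair in the same component.

    Per-source depth-limited DFS over simple paths with branch-and-bound
    pruning: a prefix whose strength drops to <= prune_epsilon is
    abandoned (exact, because extending a simple path multiplies its
    strength by a factor <= 1).  Each pair is searched from its
    lexicographically smaller endpoint only, so the stored values are
    symmetric by construction and reproduce the oracle's multiplication
    order exactly.
    """
    store = SimilarityStore()
    g = net.graph
    deg_wt = {v: net.weighted_degree(v) for v in g.nodes}
    adj = {
        v: sorted((u, d["weight"]) for u, d in g.adj[v].items()) for v in g.nodes
    }
    eps = params.prune_epsilon
    budget = params.max_expansions

    for source in sorted(g.nodes):
        lengths = nx.single_source_shortest_path_length(g, source)
        # targets still owed a value: lexicographically after the source
        windows = {
            t: l + params.theta
            for t, l in lengths.items()
            if t > source
        }
        if not windows:
            continue
        depth_limit = min(max(windows.values()), params.max_abs_depth)
        best: dict[str, float] = {t: 0.0 for t in windows}

        expansions = 0
        on_path = {source}
        # stack of (node, strength of the prefix ending at node, neighbor iter)
        stack: list[tuple[str, float, Iterator[tuple[str, float]]]] = [
            (source, params.lambda_scale, iter(adj[source]))
        ]
        while stack:
            node, s, it = stack[-1]
            depth = len(stack) - 1
            advanced = False
            for nxt, w in it:
                if nxt in on_path:
                    continue
                expansions += 1
                if expansions > budget:
                    raise SearchBudgetExceeded(
                        f"path search from {source!r} exceeded "
                        f"{budget} expansions; increase prune_epsilon"
                    )
                # node becomes interior unless it is the source itself;
                # multiplication order mirrors path_strength() exactly
                s2 = s * w if depth == 0 else s * w / deg_wt[node]
                if s2 <= eps:
                    # abandoned prefix: extensions only shrink it further
                    # (with eps == 0 this cuts exact zeros only, so the
                    # search stays equivalent to exhaustive enumeration)
                    continue
                hi = windows.get(nxt)
                if hi is not None and depth + 1 <= hi and s2 > best[nxt]:
                    best[nxt] = s2
                if depth + 1 < depth_limit:
                    on_path.add(nxt)
                    stack.append((nxt, s2, iter(adj[nxt])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                on_path.discard(node)

        for t, val in best.items():
            store.set(source, t, val, l=lengths[t])
    return store
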