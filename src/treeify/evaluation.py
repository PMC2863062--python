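"""Assessment battery: attack vulnerability, normalized modularity,
f-measure cluster accuracy, and ranked lethality/overlap profiling.

These are the observational tools used to judge whether structural hubs
are topologically and biologically meaningful and whether the extracted
clusters behave like functional modules: targeted node-removal curves of
the largest connected component, the intra-edge fraction of a node set
normalized by its chance level, best-match precision/recall harmonic
means against reference modules, and windowed/cumulative profiles of a
per-node property along a ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from treeify.graph_io import ValidationError, WeightedNetwork
from treeify.hubs_modules import ClusterSet

logger = logging.getLogger(__name__)

STRATEGIES = ("random", "degree", "hub_confidence")


@dataclass
class AttackCurve:
    """Largest-component fraction as nodes are removed by one strategy."""

    strategy: str
    points: list[tuple[int, float]]  # (removed count, LCC fraction of original |V|)
    seed: int | None = None
    removed: list[str] = field(default_factory=list)

    def fraction_at(self, removed_count: int) -> float:
        for k, f in self.points:
            if k == removed_count:
                return f
        raise KeyError(removed_count)


@dataclass
class ModularityScore:
    """Raw modularity m = E_in / E_inc and its size-normalized value m / p."""

    raw: float | None
    normalization: float
    normalized: float | None

    @property
    def defined(self) -> bool:
        return self.raw is not None


def _lcc_fraction(g: nx.Graph, n_original: int) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    return max(len(c) for c in nx.connected_components(g)) / n_original


def attack_simulation(
    net: WeightedNetwork,
    strategy: str,
    steps: int,
    seed: int | None = None,
    ranking: list[str] | None = None,
    recompute: bool = False,
    params=None,
) -> AttackCurve:
    """Remove ``steps`` nodes one at a time and track the largest component.

    Strategies: ``random`` (seeded uniform choice among remaining nodes),
    ``degree`` (current highest degree, recomputed after every removal),
    ``hub_confidence`` (descending hub-confidence order computed once on
    the intact network by default; ``recompute=True`` re-ranks after each
    removal, which is quadratically more expensive).  A precomputed
    ``ranking`` short-circuits the hub-confidence computation.  Fractions
    are relative to the original node count, so a connected input starts
    at exactly 1.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(
            f"unknown strategy {strategy!r}; choose from {STRATEGIES}"
        )
    if steps > net.n_nodes:
        raise ValidationError("cannot remove more nodes than the network has")

    g = net.graph.copy()
    n0 = net.n_nodes
    rng = np.random.default_rng(seed)

    def hub_ranking(current: nx.Graph) -> list[str]:
        from treeify.hierarchy import build_tree
        from treeify.hubs_modules import rank_hubs
        from treeify.path_strength import PathStrengthParams, all_pairs_similarity

        sub = WeightedNetwork(
            ((u, v, d["weight"]) for u, v, d in current.edges(data=True)),
            nodes=current.nodes,
        )
        p = params if params is not None else PathStrengthParams()
        store = all_pairs_similarity(sub, p)
        return rank_hubs(build_tree(sub, store), store).ranking

    static_rank: list[str] | None = None
    if strategy == "hub_confidence" and not recompute:
        static_rank = ranking if ranking is not None else hub_ranking(g)

    points = [(0, _lcc_fraction(g, n0))]
    removed: list[str] = []
    for step in range(1, steps + 1):
        if strategy == "random":
            victim = str(rng.choice(sorted(g.nodes)))
        elif strategy == "degree":
            victim = max(sorted(g.nodes), key=g.degree)
        else:  # hub_confidence
            if recompute:
                victim = hub_ranking(g)[0]
            else:
                assert static_rank is not None
                victim = next(n for n in static_rank if n in g)
        g.remove_node(victim)
        removed.append(victim)
        points.append((step, _lcc_fraction(g, n0)))
    return AttackCurve(strategy=strategy, points=points, seed=seed, removed=removed)


def normalized_modularity(
    net: WeightedNetwork, members: set[str] | frozenset[str]
) -> ModularityScore:
    """m = E_in / E_inc normalized by the chance level p = (|S|-1)/(|V|-1).

    E_in counts edges with both endpoints in the member set; E_inc counts
    edges with at least one endpoint in it (each edge once).  p is the
    probability that a uniformly chosen potential partner of a member lies
    inside the set, so m / p corrects the raw ratio for set size.  With no
    incident edge at all the score is undefined (None).
    """
    members = set(members)
    if not 2 <= len(members) < net.n_nodes:
        raise ValidationError(
            "member set must have >= 2 nodes and be a proper subset"
        )
    e_in = e_inc = 0
    for u, v, _ in net.edges():
        inside = (u in members) + (v in members)
        if inside == 2:
            e_in += 1
        if inside >= 1:
            e_inc += 1
    p = (len(members) - 1) / (net.n_nodes - 1)
    if e_inc == 0:
        return ModularityScore(raw=None, normalization=p, normalized=None)
    m = e_in / e_inc
    return ModularityScore(raw=m, normalization=p, normalized=m / p)


def modularity_by_depth(
    net: WeightedNetwork, clusters: ClusterSet
) -> list[tuple[int, float]]:
    """Mean normalized modularity per cluster-depth group, depth ascending.

    Clusters whose modularity is undefined, or whose size falls outside
    the [2, |V|) window the score is defined on, are skipped.
    """
    if len(clusters) == 0:
        raise ValidationError("no clusters to evaluate")
    groups: dict[int, list[float]] = {}
    for c in clusters:
        if not 2 <= len(c.members) < net.n_nodes:
            continue
        score = normalized_modularity(net, c.members)
        if score.defined:
            groups.setdefault(c.depth, []).append(score.normalized)
    return [(d, float(np.mean(v))) for d, v in sorted(groups.items())]


def f_measure(cluster: set[str] | frozenset[str], module: set[str] | frozenset[str]) -> float:
    """Harmonic mean of precision (overlap/|cluster|) and recall (overlap/|module|)."""
    if not cluster or not module:
        raise ValidationError("f-measure of an empty set is undefined")
    overlap = len(set(cluster) & set(module))
    if overlap == 0:
        return 0.0
    p = overlap / len(cluster)
    r = overlap / len(module)
    return 2 * p * r / (p + r)


def clustering_accuracy(
    clusters: ClusterSet | list[frozenset[str]],
    modules: dict[str, set[str]],
    levels: dict[str, int] | None = None,
) -> dict[int | None, float]:
    """Mean best-match f-measure of reference modules against clusters.

    For each reference module the best-matching cluster (max f-measure) is
    found; the mean over modules is reported per annotation level when
    ``levels`` maps module names to levels, otherwise under the single key
    ``None``.  Modules with fewer than 2 members are ignored.  With no
    clusters at all, accuracy is 0 (warned).
    """
    member_sets = (
        clusters.member_sets() if isinstance(clusters, ClusterSet) else list(clusters)
    )
    usable = {name: m for name, m in modules.items() if len(m) >= 2}
    if not usable:
        raise ValidationError("need at least one reference module with >= 2 members")
    if not member_sets:
        logger.warning("no clusters; accuracy is 0 for every level")
        lvls = {levels.get(n) for n in usable} if levels else {None}
        return {lv: 0.0 for lv in lvls}

    best: dict[str, float] = {
        name: max(f_measure(c, m) for c in member_sets) for name, m in usable.items()
    }
    by_level: dict[int | None, list[float]] = {}
    for name, f in best.items():
        lv = levels.get(name) if levels else None
        by_level.setdefault(lv, []).append(f)
    return {lv: float(np.mean(v)) for lv, v in sorted(by_level.items(), key=str)}


@dataclass
class RankedProfile:
    """Windowed and cumulative summaries of a property along a ranking."""

    window: int
    window_means: list[float]
    cumulative_means: list[float]
    n_missing: int = 0


def ranked_property_profile(
    ranking: list[str],
    values: dict[str, float | bool],
    window: int,
) -> RankedProfile:
    """Proportions (for flags) or running means (for counts) along a ranking.

    Nodes absent from ``values`` are excluded (logged).  ``window_means``
    averages each consecutive block of ``window`` ranked nodes (the last
    block may be shorter); ``cumulative_means`` is the running mean after
    each node.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    present = [n for n in ranking if n in values]
    n_missing = len(ranking) - len(present)
    if n_missing:
        logger.warning("%d ranked node(s) lack a value; excluded", n_missing)
    xs = np.array([float(values[n]) for n in present])
    if xs.size == 0:
        return RankedProfile(window, [], [], n_missing)
    cum = list(np.cumsum(xs) / np.arange(1, xs.size + 1))
    wins = [float(np.mean(xs[i : i + window])) for i in range(0, xs.size, window)]
    return RankedProfile(
        window=window,
        window_means=wins,
        cumulative_means=[float(c) for c in cum],
        n_missing=n_missing,
    )
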