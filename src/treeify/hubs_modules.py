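"""Structural-hub scoring and nested-module extraction from a hierarchy tree.

The hub confidence H(a) of a node is the summed functional similarity to
its tree descendants divided by its similarity to its parent; the root
uses its centrality (sum over all other nodes) instead.  Leaves have no
descendants and score 0.  Clusters are emitted in descending-H order as
the hub plus its descendant subtree, until the first node falls below a
user-specified threshold; as subtrees of one tree they form a laminar
family, and nested modules are reported at their depth in the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from treeify.graph_io import ValidationError
from treeify.hierarchy import HierarchyTree, centrality
from treeify.path_strength import SimilarityStore


@dataclass
class HubReport:
    """Per-node hub confidence with a deterministic ranking.

    ``ranking`` orders nodes by confidence descending, node id ascending.
    """

    confidence: dict[str, float]
    ranking: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ranking:
            self.ranking = sorted(
                self.confidence, key=lambda n: (-self.confidence[n], n)
            )

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node\thub_confidence\trank\n")
            for i, n in enumerate(self.ranking, start=1):
                fh.write(f"{n}\t{self.confidence[n]:.10g}\t{i}\n")


@dataclass(frozen=True)
class Cluster:
    """A hub together with its descendant subtree, tagged with tree depth."""

    hub: str
    members: frozenset[str]
    depth: int
    confidence: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.clusters]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("hub\tdepth\thub_confidence\tmembers\n")
            for c in self.clusters:
                fh.write(
                    f"{c.hub}\t{c.depth}\t{c.confidence:.10g}\t"
                    + ",".join(sorted(c.members))
                    + "\n"
                )


def descendants(tree: HierarchyTree, a: str) -> set[str]:
    """All nodes whose parent chain reaches ``a``; empty for leaves."""
    if a not in tree.parent:
        raise ValidationError(f"unknown node {a!r}")
    out: set[str] = set()
    stack = list(tree.children[a])
    while stack:
        v = stack.pop()
        out.add(v)
        stack.extend(tree.children[v])
    return out


def hub_confidence(tree: HierarchyTree, store: SimilarityStore, a: str) -> float:
    """H(a): leaf -> 0; root -> centrality; else sum F(a, L_a) / F(a, parent)."""
    if a not in tree.parent:
        raise ValidationError(f"unknown node {a!r}")
    if tree.is_leaf(a):
        return 0.0
    if tree.parent[a] is None:
        return centrality(store, a)
    num = sum(store.get(a, x) for x in descendants(tree, a))
    return num / store.get(a, tree.parent[a])


def rank_hubs(tree: HierarchyTree, store: SimilarityStore) -> HubReport:
    """Score every node and rank by confidence descending, id ascending."""
    conf = {n: hub_confidence(tree, store, n) for n in tree.parent}
    return HubReport(confidence=conf)


def cluster_depth(tree: HierarchyTree, members: set[str] | frozenset[str]) -> int:
    """Maximum node depth (longest downward path to a leaf) among members."""
    if not members:
        raise ValidationError("cluster depth of an empty set is undefined")
    return max(tree.node_depth(m) for m in members)


def extract_clusters(
    tree: HierarchyTree,
    store: SimilarityStore,
    h_threshold: float,
    report: HubReport | None = None,
) -> ClusterSet:
    """Emit {hub} | L_hub per node in descending-H order while H >= threshold.

    Clusters are deliberately not deduplicated against each other: nesting
    is the point, and the laminar structure carries the hierarchy.  With
    ``h_threshold == 0`` every node qualifies, so leaves emit singleton
    clusters; any positive threshold excludes them (leaves score 0).
    """
    if h_threshold < 0:
        raise ValidationError("h_threshold must be >= 0")
    if report is None:
        report = rank_hubs(tree, store)
    out: list[Cluster] = []
    for node in report.ranking:
        h = report.confidence[node]
        if h < h_threshold:
            break
        members = frozenset({node} | descendants(tree, node))
        out.append(
            Cluster(
                hub=node,
                members=members,
                depth=cluster_depth(tree, members),
                confidence=h,
            )
        )
    return ClusterSet(clusters=out)
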