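"""Network-to-tree conversion by path-strength centrality.

The centrality C(a) of a node is the sum of its functional similarities to
every other node.  Nodes are totally ordered by centrality (descending,
node id ascending on ties); each non-root node takes as parent the node it
is most similar to among the nodes preceding it in that order within its
connected component.  The component-wise maximum has no parent and becomes
that component's root, so every component yields exactly one tree and the
parent pointers can never cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from treeify.graph_io import ValidationError, WeightedNetwork
from treeify.path_strength import SimilarityStore


@dataclass
class HierarchyTree:
    """Result of converting a weighted network into a hierarchy.

    ``order`` is the deterministic total order on nodes (centrality
    descending, id ascending); ``parent`` maps every non-root to the
    most-similar node preceding it in that order within its component.
    """

    centralities: dict[str, float]
    parent: dict[str, str | None]
    roots: set[str]
    order: list[str] = field(default_factory=list)
    children: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = {n: [] for n in self.parent}
            for n, p in self.parent.items():
                if p is not None:
                    self.children[p].append(n)
            for kids in self.children.values():
                kids.sort()

    def is_leaf(self, node: str) -> bool:
        return not self.children[node]

    def nodes(self) -> list[str]:
        return list(self.order)

    def node_depth(self, node: str) -> int:
        """Longest downward path (in edges) from ``node`` to a leaf."""
        if node not in self.parent:
            raise ValidationError(f"unknown node {node!r}")
        if node not in self._depths:
            # iterative post-order to avoid recursion limits on chains
            stack = [node]
            while stack:
                v = stack[-1]
                pending = [c for c in self.children[v] if c not in self._depths]
                if pending:
                    stack.extend(pending)
                else:
                    self._depths[v] = (
                        1 + max(self._depths[c] for c in self.children[v])
                        if self.children[v]
                        else 0
                    )
                    stack.pop()
        return self._depths[node]

    @property
    def _depths(self) -> dict[str, int]:
        if not hasattr(self, "_depth_cache"):
            self._depth_cache: dict[str, int] = {}
        return self._depth_cache

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tparent\tcentrality\n")
            for n in self.order:
                p = self.parent[n] if self.parent[n] is not None else "-"
                fh.write(f"{n}\t{p}\t{self.centralities[n]:.10g}\n")

    def to_newick(self) -> str:
        """Newick string of the forest (one tree per root, ';'-terminated each)."""

        def render(v: str) -> str:
            kids = self.children[v]
            if not kids:
                return v
            return "(" + ",".join(render(c) for c in kids) + ")" + v

        return "".join(render(r) + ";" for r in sorted(self.roots))


def centrality(store: SimilarityStore, node: str) -> float:
    """C(a) = sum of F(a, b) over all b != a (cross-component terms are 0)."""
    total = 0.0
    for key, v in store.values.items():
        if node in key:
            total += v
    return total


def build_tree(net: WeightedNetwork, store: SimilarityStore) -> HierarchyTree:
    """Convert a weighted network into a hierarchy tree.

    Each node's ancestor candidates are the nodes strictly preceding it in
    the total order within its own component; the parent is the candidate
    with maximal F, ties broken by node id ascending.
    """
    if net.n_nodes == 0:
        raise ValidationError("cannot build a tree from an empty network")

    cent = {n: centrality(store, n) for n in net.nodes}
    order = sorted(cent, key=lambda n: (-cent[n], n))
    rank = {n: i for i, n in enumerate(order)}

    parent: dict[str, str | None] = {}
    roots: set[str] = set()
    for comp in net.components():
        comp_sorted = sorted(comp, key=rank.__getitem__)
        root = comp_sorted[0]
        parent[root] = None
        roots.add(root)
        for i, a in enumerate(comp_sorted[1:], start=1):
            best: str | None = None
            best_f = -1.0
            for t in comp_sorted[:i]:  # nodes strictly preceding a
                f = store.get(a, t)
                if f > best_f or (f == best_f and (best is None or t < best)):
                    best, best_f = t, f
            parent[a] = best

    return HierarchyTree(centralities=cent, parent=parent, roots=roots, order=order)
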