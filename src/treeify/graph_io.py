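"""Readers and writers for weighted networks, annotations, and expression data.

The canonical network format is a 2- or 3-column whitespace/tab-separated
edge list (``nodeA  nodeB  [weight]``); SIF (``nodeA  relation  nodeB``) is
accepted read-only with implied weight 1.0.  Node identifiers are opaque,
case-sensitive strings; no identifier mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class WeightedNetwork:
    """Undirected network with per-edge weights in [0, 1].

    A thin wrapper around :class:`networkx.Graph` that enforces the
    invariants the downstream algorithms depend on: no self-loops, no
    duplicate edges, and weights within the unit interval.

    Parameters
    ----------
    edges
        Iterable of ``(u, v, weight)`` triples.  Duplicate unordered pairs
        are merged keeping the maximum weight; self-loops are dropped with
        a warning (the nodes are retained).
    nodes
        Optional extra node ids (isolated nodes are legal).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        for u, v, w in edges:
            u, v = str(u), str(v)
            if u == v:
                logger.warning("dropping self-loop on node %r", u)
                g.add_node(u)
                continue
            w = float(w)
            if g.has_edge(u, v):
                w = max(w, g[u][v]["weight"])
            g.add_edge(u, v, weight=w)
        g.add_nodes_from(str(n) for n in nodes)
        for u, v, d in g.edges(data=True):
            if not (0.0 <= d["weight"] <= 1.0):
                raise ValidationError(
                    f"edge ({u}, {v}) weight {d['weight']} outside [0, 1]"
                )
        self.graph = g

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["weight"]

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def neighbors(self, v: str) -> set[str]:
        return set(self.graph.neighbors(v))

    def weighted_degree(self, v: str) -> float:
        """d_wt(v): sum of the weights of edges incident to ``v``."""
        return sum(d["weight"] for _, _, d in self.graph.edges(v, data=True))

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def subgraph(self, nodes: Iterable[str]) -> "WeightedNetwork":
        sub = self.graph.subgraph(nodes)
        return WeightedNetwork(
            ((u, v, d["weight"]) for u, v, d in sub.edges(data=True)),
            nodes=sub.nodes,
        )

    def copy(self) -> "WeightedNetwork":
        return self.subgraph(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __repr__(self) -> str:
        return f"WeightedNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class AnnotationTable:
    """Node -> set-of-terms mapping plus an optional lethality flag.

    ``terms`` maps each annotated node to its set of function terms.  Nodes
    absent from the table implicitly map to the empty set.  ``term_levels``
    optionally records the hierarchical level of each term (smaller level =
    more general function).  ``lethal`` optionally flags essential nodes.
    """

    terms: dict[str, set[str]] = field(default_factory=dict)
    term_levels: dict[str, int] = field(default_factory=dict)
    lethal: dict[str, bool] = field(default_factory=dict)

    def terms_of(self, node: str) -> set[str]:
        return self.terms.get(node, set())

    def is_lethal(self, node: str) -> bool | None:
        return self.lethal.get(node)

    def modules(self, level: int | None = None) -> dict[str, set[str]]:
        """Invert the table: term -> set of annotated nodes.

        When ``level`` is given, only terms recorded at that level are
        returned (terms with no recorded level are never filtered out by a
        ``level=None`` call but are excluded from any levelled call).
        """
        out: dict[str, set[str]] = {}
        for node, ts in self.terms.items():
            for t in ts:
                if level is not None and self.term_levels.get(t) != level:
                    continue
                out.setdefault(t, set()).add(node)
        return out


@dataclass
class ExpressionMatrix:
    """Per-node expression profiles over a common set of conditions."""

    profiles: dict[str, list[float]]
    conditions: list[str]

    def __post_init__(self) -> None:
        k = len(self.conditions)
        for node, vec in self.profiles.items():
            if len(vec) != k:
                raise ValidationError(
                    f"profile for {node!r} has {len(vec)} values, expected {k}"
                )

    def __contains__(self, node: str) -> bool:
        return node in self.profiles

    def profile(self, node: str) -> list[float]:
        return self.profiles[node]


# ---------------------------------------------------------------------------
# readers / writers


def _rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_weighted_network(
    path: str | Path, normalize: bool = False
) -> WeightedNetwork:
    """Read a 2- or 3-column edge list into a :class:`WeightedNetwork`.

    Two-column rows imply weight 1.0.  With ``normalize=True`` weights are
    min-max scaled into [0, 1] over the whole file (a constant weight
    column maps to 1.0); without it an out-of-range weight raises
    :class:`ValidationError`.  Duplicate pairs keep the maximum weight and
    self-loops are dropped with a logged warning.
    """
    triples: list[tuple[str, str, float]] = []
    for lineno, parts in _rows(path):
        if len(parts) == 2:
            u, v, w = parts[0], parts[1], 1.0
        elif len(parts) == 3:
            u, v = parts[0], parts[1]
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}, line {lineno}: weight {parts[2]!r} is not a number"
                ) from exc
        else:
            raise ParseError(
                f"{path}, line {lineno}: expected 2 or 3 columns, got {len(parts)}"
            )
        triples.append((u, v, w))

    if normalize and triples:
        ws = [w for _, _, w in triples]
        lo, hi = min(ws), max(ws)
        if hi > lo:
            triples = [(u, v, (w - lo) / (hi - lo)) for u, v, w in triples]
        else:
            triples = [(u, v, 1.0) for u, v, _ in triples]
    else:
        for u, v, w in triples:
            if not (0.0 <= w <= 1.0):
                raise ValidationError(
                    f"{path}: edge ({u}, {v}) weight {w} outside [0, 1]; "
                    "pass normalize=True to rescale"
                )
    return WeightedNetwork(triples)


def read_sif(path: str | Path) -> WeightedNetwork:
    """Read a SIF file (``nodeA  relation  nodeB``); all weights are 1.0."""
    triples = []
    for lineno, parts in _rows(path):
        if len(parts) != 3:
            raise ParseError(
                f"{path}, line {lineno}: SIF rows need 3 columns, got {len(parts)}"
            )
        triples.append((parts[0], parts[2], 1.0))
    return WeightedNetwork(triples)


def write_weighted_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write a network as a 3-column TSV, edges sorted for determinism."""
    rows = sorted((min(u, v), max(u, v), w) for u, v, w in net.edges())
    with open(path, "w") as fh:
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.6f}\n")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a two-column ``node  term`` file (set semantics on duplicates)."""
    terms: dict[str, set[str]] = {}
    empty = True
    for lineno, parts in _rows(path):
        if len(parts) != 2:
            raise ParseError(
                f"{path}, line {lineno}: expected 2 columns, got {len(parts)}"
            )
        empty = False
        terms.setdefault(parts[0], set()).add(parts[1])
    if empty:
        raise ValidationError(f"{path}: annotation file is empty")
    return AnnotationTable(terms=terms)


def read_lethality(path: str | Path, into: AnnotationTable | None = None) -> AnnotationTable:
    """Read a ``node  0|1`` lethality file, optionally merging into a table."""
    table = into if into is not None else AnnotationTable()
    empty = True
    for lineno, parts in _rows(path):
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ParseError(
                f"{path}, line {lineno}: expected 'node 0|1', got {parts!r}"
            )
        empty = False
        table.lethal[parts[0]] = parts[1] == "1"
    if empty:
        raise ValidationError(f"{path}: lethality file is empty")
    return table


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table: header of condition labels, one row per node.

    Rows containing non-numeric cells are dropped with a logged count.
    Fewer than 3 conditions is an error (correlations would be fragile).
    """
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    if df.shape[1] < 3:
        raise ValidationError(
            f"{path}: {df.shape[1]} condition columns; at least 3 required"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "%s: dropped %d row(s) with non-numeric values", path, int(bad.sum())
        )
    numeric = numeric[~bad]
    return ExpressionMatrix(
        profiles={str(i): [float(x) for x in row] for i, row in numeric.iterrows()},
        conditions=[str(c) for c in df.columns],
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(expr.conditions) + "\n")
        for node in sorted(expr.profiles):
            vals = "\t".join(f"{x:.6f}" for x in expr.profiles[node])
            fh.write(f"{node}\t{vals}\n")


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for node in sorted(table.terms):
            for term in sorted(table.terms[node]):
                fh.write(f"{node}\t{term}\n")


def write_lethality(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for node in sorted(table.lethal):
            fh.write(f"{node}\t{int(table.lethal[node])}\n")
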