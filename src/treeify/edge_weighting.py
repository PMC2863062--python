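"""Edge-weighting schemes and their functional-consistency evaluation.

Two weighting schemes are provided for unweighted interaction networks:

* hypergeometric: the significance of the shared neighborhood of an
  interacting pair.  With n = |V| nodes, reduced neighbor sets (the two
  endpoints removed) of sizes a and b sharing s members, P is the
  upper-tail hypergeometric probability of observing >= s shared
  neighbors by chance; the weight is 1 - P, so a significantly
  co-wired pair gets a weight near 1.
* co-expression: the Pearson correlation r of the endpoints' expression
  profiles mapped affinely onto [0, 1] by (r + 1) / 2.

Any weighting can be assessed against annotations through functional
consistency — the Jaccard index of the endpoints' term sets — accumulated
over edges ranked by descending weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from treeify.graph_io import (
    AnnotationTable,
    ExpressionMatrix,
    ValidationError,
    WeightedNetwork,
)

logger = logging.getLogger(__name__)

#: sentinel for a consistency value that is undefined (both term sets empty)
UNDEFINED = None


@dataclass
class WeightingResult:
    """Edge -> weight mapping for one scheme over one network."""

    weights: dict[frozenset[str], float]
    scheme: str
    params: dict = field(default_factory=dict)

    def get(self, u: str, v: str) -> float:
        return self.weights[frozenset((u, v))]

    def apply(self, net: WeightedNetwork) -> WeightedNetwork:
        """Return a copy of ``net`` carrying these weights."""
        return WeightedNetwork(
            ((u, v, self.get(u, v)) for u, v, _ in net.edges()),
            nodes=net.nodes,
        )

    def items(self):
        return self.weights.items()


def hypergeometric_weight(net: WeightedNetwork) -> WeightingResult:
    """Weight each edge by the significance of its shared neighborhood.

    For edge (v_i, v_j): s = |N(v_i) ∩ N(v_j)| over the reduced neighbor
    sets (endpoints removed), a and b their sizes, n = |V|;
    P = Pr[X >= s] for X ~ Hypergeom(n, a, b) and weight = 1 - P,
    clamped to [0, 1].  With s = 0 the tail is total probability and the
    weight is 0.
    """
    if net.n_nodes < 3:
        raise ValidationError("hypergeometric weighting needs >= 3 nodes")
    n = net.n_nodes
    weights: dict[frozenset[str], float] = {}
    for u, v, _ in net.edges():
        nu = net.neighbors(u) - {u, v}
        nv = net.neighbors(v) - {u, v}
        s = len(nu & nv)
        a, b = len(nu), len(nv)
        # Pr[X >= s], X ~ Hypergeom(M=n, n=a, N=b)
        p = float(stats.hypergeom.sf(s - 1, n, a, b))
        weights[frozenset((u, v))] = min(1.0, max(0.0, 1.0 - p))
    return WeightingResult(weights=weights, scheme="hypergeom", params={"n": n})


def coexpression_weight(
    net: WeightedNetwork, expr: ExpressionMatrix
) -> WeightingResult:
    """Weight each edge by (r + 1) / 2, r the Pearson correlation of profiles.

    Edges with an endpoint missing from the expression matrix get weight 0
    (logged); constant profiles have undefined r, treated as 0 so the edge
    gets the neutral weight 0.5 (logged).
    """
    weights: dict[frozenset[str], float] = {}
    n_missing = n_constant = 0
    for u, v, _ in net.edges():
        key = frozenset((u, v))
        if u not in expr or v not in expr:
            weights[key] = 0.0
            n_missing += 1
            continue
        x = np.asarray(expr.profile(u), dtype=float)
        y = np.asarray(expr.profile(v), dtype=float)
        if x.shape != y.shape:
            raise ValidationError(
                f"profile lengths differ for edge ({u}, {v}): "
                f"{x.size} vs {y.size}"
            )
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            r = 0.0
            n_constant += 1
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        weights[key] = min(1.0, max(0.0, (r + 1.0) / 2.0))
    if n_missing:
        logger.warning("%d edge(s) missing expression; weight set to 0", n_missing)
    if n_constant:
        logger.warning(
            "%d edge(s) with a constant profile; r treated as 0", n_constant
        )
    return WeightingResult(weights=weights, scheme="coexpr", params={})


def functional_consistency(
    a_terms: set[str], b_terms: set[str]
) -> float | None:
    """Jaccard index of two term sets; None (undefined) when both are empty.

    The undefined sentinel is deliberately distinct from 0: a pair with no
    annotation carries no evidence either way and must be excluded from
    averages rather than dragging them down.
    """
    if not a_terms and not b_terms:
        return UNDEFINED
    inter = len(a_terms & b_terms)
    union = len(a_terms | b_terms)
    return inter / union


def consistency_curve(
    weights: WeightingResult, ann: AnnotationTable
) -> list[tuple[float, float]]:
    """Cumulative mean functional consistency over edges ranked by weight.

    Edges are sorted by weight descending (ties by lexicographic edge id);
    edges whose consistency is undefined (neither endpoint annotated) are
    excluded.  Returns (rank fraction, cumulative mean consistency) per
    prefix of the remaining edges.
    """
    scored: list[tuple[float, tuple[str, str], float]] = []
    for key, w in weights.items():
        u, v = sorted(key)
        c = functional_consistency(ann.terms_of(u), ann.terms_of(v))
        if c is None:
            continue
        scored.append((w, (u, v), c))
    if not scored:
        raise ValidationError("no edge with an annotated endpoint")
    scored.sort(key=lambda t: (-t[0], t[1]))
    curve: list[tuple[float, float]] = []
    total = 0.0
    for i, (_, _, c) in enumerate(scored, start=1):
        total += c
        curve.append((i / len(scored), total / i))
    return curve
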