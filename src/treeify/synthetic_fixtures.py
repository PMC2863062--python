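"""Seeded generators for networks with planted hierarchical modules.

Real interactome benchmarks (curated interaction sets, function catalogs,
expression compendia) are external downloads; the generators here emulate
the structure those data are assumed to have, so every algorithm in the
package can be exercised and validated without network access:

* a two-level hierarchy of modules containing sub-modules, with dense,
  strongly weighted edges inside sub-modules, sparser and weaker edges
  across sub-modules of one module, and rare weak edges between modules;
* one designated hub per module, wired to most module members and to the
  other hubs, mirroring the bridging role of intermodule hubs;
* annotations: one term per module (level 1) and per sub-module (level 2)
  given to members; hubs collect the terms of every module they touch, so
  they overlap more functions than ordinary nodes;
* lethality flags concentrated on hubs;
* expression profiles from a module latent factor plus a sub-module
  offset and node-level Gaussian noise, so co-expression weighting can
  recover module structure by construction.

All randomness flows through one seeded NumPy generator; the same spec and
seed reproduce the fixture byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import networkx as nx
import numpy as np

from treeify.graph_io import (
    AnnotationTable,
    ExpressionMatrix,
    ValidationError,
    WeightedNetwork,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-hierarchy generator (the "easy" preset).

    Defaults give 3 modules x 2 sub-modules x 6 nodes plus one hub and two
    peripheral degree-1 nodes per module (45 nodes): sub-modules are
    near-cliques with strong weights, cross-sub-module and cross-module
    edges are progressively sparser and weaker, hubs connect to 80% of
    their module and to every other hub, and each peripheral node hangs
    off a single module member — mirroring the low-degree periphery of
    real interactomes.
    """

    n_modules: int = 3
    submodules_per_module: int = 2
    nodes_per_submodule: int = 6
    p_intra_sub: float = 0.9
    w_intra_sub: tuple[float, float] = (0.7, 0.95)
    p_intra_mod: float = 0.3
    w_intra_mod: tuple[float, float] = (0.4, 0.6)
    p_inter_mod: float = 0.04
    w_inter_mod: tuple[float, float] = (0.05, 0.2)
    hub_member_fraction: float = 0.8
    w_hub: tuple[float, float] = (0.6, 0.9)
    w_hub_hub: tuple[float, float] = (0.3, 0.5)
    n_peripheral_per_module: int = 2
    lethal_fraction_hubs: float = 0.8
    lethal_fraction_other: float = 0.1
    n_conditions: int = 12
    expression_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.submodules_per_module < 1:
            raise ValidationError("need at least one module and sub-module")
        if self.nodes_per_submodule < 1:
            raise ValidationError("sub-modules need at least one node")
        for p in (self.p_intra_sub, self.p_intra_mod, self.p_inter_mod,
                  self.hub_member_fraction, self.lethal_fraction_hubs,
                  self.lethal_fraction_other):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.w_intra_sub, self.w_intra_mod, self.w_inter_mod,
                       self.w_hub, self.w_hub_hub):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError(f"weight range ({lo}, {hi}) invalid")


@dataclass
class PlantedTruth:
    """Ground truth of a generated fixture, for recovery tests."""

    modules: dict[str, set[str]]      # module term -> member nodes (incl. hub)
    submodules: dict[str, set[str]]   # sub-module term -> member nodes
    hubs: list[str]                   # one designated hub per module
    spec: dict = field(default_factory=dict)


def _node_name(mod: int, sub: int, idx: int) -> str:
    return f"m{mod}s{sub}n{idx:02d}"


def generate(
    spec: FixtureSpec,
) -> tuple[WeightedNetwork, AnnotationTable, ExpressionMatrix, PlantedTruth]:
    """Generate a planted-hierarchy fixture from a spec (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)

    # --- membership ----------------------------------------------------
    submembers: dict[tuple[int, int], list[str]] = {}
    hubs: list[str] = []
    for m in range(spec.n_modules):
        for s in range(spec.submodules_per_module):
            submembers[(m, s)] = [
                _node_name(m, s, i) for i in range(spec.nodes_per_submodule)
            ]
        hubs.append(f"m{m}hub")
    module_members = {
        m: [n for s in range(spec.submodules_per_module) for n in submembers[(m, s)]]
        for m in range(spec.n_modules)
    }

    def uniform(rng_, lo_hi: tuple[float, float]) -> float:
        return float(rng_.uniform(*lo_hi))

    edges: dict[frozenset[str], float] = {}

    def add_edge(u: str, v: str, w: float) -> None:
        key = frozenset((u, v))
        edges[key] = max(w, edges.get(key, 0.0))

    # intra-sub-module: near-clique with strong weights
    for (m, s), nodes in submembers.items():
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                if rng.random() < spec.p_intra_sub:
                    add_edge(u, v, uniform(rng, spec.w_intra_sub))
        # guarantee internal connectivity with a seeded spanning chain
        for u, v in zip(nodes, nodes[1:]):
            if frozenset((u, v)) not in edges:
                add_edge(u, v, uniform(rng, spec.w_intra_sub))

    # cross-sub-module within a module
    for m in range(spec.n_modules):
        for s1 in range(spec.submodules_per_module):
            for s2 in range(s1 + 1, spec.submodules_per_module):
                for u in submembers[(m, s1)]:
                    for v in submembers[(m, s2)]:
                        if rng.random() < spec.p_intra_mod:
                            add_edge(u, v, uniform(rng, spec.w_intra_mod))

    # cross-module background
    for m1 in range(spec.n_modules):
        for m2 in range(m1 + 1, spec.n_modules):
            for u in module_members[m1]:
                for v in module_members[m2]:
                    if rng.random() < spec.p_inter_mod:
                        add_edge(u, v, uniform(rng, spec.w_inter_mod))

    # hubs: wired to a fraction of their module's members and to all hubs
    for m, hub in enumerate(hubs):
        members = module_members[m]
        k = max(1, round(spec.hub_member_fraction * len(members)))
        chosen = rng.choice(members, size=k, replace=False)
        for v in sorted(str(x) for x in chosen):
            add_edge(hub, v, uniform(rng, spec.w_hub))
    for i, h1 in enumerate(hubs):
        for h2 in hubs[i + 1 :]:
            add_edge(h1, h2, uniform(rng, spec.w_hub_hub))

    # peripheral degree-1 nodes: each hangs off one member of its module
    peripheral_home: dict[str, tuple[int, int]] = {}
    for m in range(spec.n_modules):
        for i in range(spec.n_peripheral_per_module):
            s = int(rng.integers(spec.submodules_per_module))
            host = str(rng.choice(submembers[(m, s)]))
            name = f"m{m}p{i}"
            add_edge(name, host, uniform(rng, spec.w_intra_mod))
            peripheral_home[name] = (m, s)

    all_nodes = sorted(
        {n for ns in submembers.values() for n in ns}
        | set(hubs)
        | set(peripheral_home)
    )
    net = WeightedNetwork(
        ((u, v, w) for (u, v), w in ((tuple(sorted(k)), w) for k, w in edges.items())),
        nodes=all_nodes,
    )

    # connectivity guarantee: bridge remaining components via weak edges
    comps = net.components()
    while len(comps) > 1:
        comps.sort(key=lambda c: sorted(c)[0])
        u = sorted(comps[0])[0]
        v = sorted(comps[1])[0]
        add_edge(u, v, uniform(rng, spec.w_inter_mod))
        net = WeightedNetwork(
            ((a, b, w) for (a, b), w in ((tuple(sorted(k)), w) for k, w in edges.items())),
            nodes=all_nodes,
        )
        comps = net.components()

    # --- annotations ----------------------------------------------------
    ann = AnnotationTable()
    for m in range(spec.n_modules):
        mterm = f"M{m}"
        ann.term_levels[mterm] = 1
        for node in module_members[m] + [hubs[m]]:
            ann.terms.setdefault(node, set()).add(mterm)
        for s in range(spec.submodules_per_module):
            sterm = f"M{m}.{s}"
            ann.term_levels[sterm] = 2
            for node in submembers[(m, s)]:
                ann.terms.setdefault(node, set()).add(sterm)
    for name, (m, s) in peripheral_home.items():
        ann.terms.setdefault(name, set()).update({f"M{m}", f"M{m}.{s}"})
    # hubs collect every term of modules they touch: their own module's
    # sub-module terms plus the module terms of the hubs they link to
    for m, hub in enumerate(hubs):
        terms = ann.terms.setdefault(hub, set())
        for s in range(spec.submodules_per_module):
            terms.add(f"M{m}.{s}")
        for m2 in range(spec.n_modules):
            terms.add(f"M{m2}")

    # --- lethality ------------------------------------------------------
    hubset = set(hubs)
    for node in all_nodes:
        frac = (
            spec.lethal_fraction_hubs if node in hubset else spec.lethal_fraction_other
        )
        ann.lethal[node] = bool(rng.random() < frac)

    # --- expression -----------------------------------------------------
    module_latent = {
        m: rng.normal(0.0, 1.0, size=spec.n_conditions)
        for m in range(spec.n_modules)
    }
    sub_offset = {
        key: rng.normal(0.0, 0.5, size=spec.n_conditions) for key in submembers
    }
    profiles: dict[str, list[float]] = {}
    for (m, s), nodes in submembers.items():
        base = module_latent[m] + sub_offset[(m, s)]
        for node in nodes:
            noise = rng.normal(0.0, spec.expression_sigma, size=spec.n_conditions)
            profiles[node] = [float(x) for x in base + noise]
    for m, hub in enumerate(hubs):
        noise = rng.normal(0.0, spec.expression_sigma, size=spec.n_conditions)
        profiles[hub] = [float(x) for x in module_latent[m] + noise]
    for name, (m, s) in peripheral_home.items():
        noise = rng.normal(0.0, spec.expression_sigma, size=spec.n_conditions)
        profiles[name] = [
            float(x) for x in module_latent[m] + sub_offset[(m, s)] + noise
        ]
    expr = ExpressionMatrix(
        profiles=profiles,
        conditions=[f"cond{i:02d}" for i in range(spec.n_conditions)],
    )

    modules_truth = {
        f"M{m}": set(module_members[m]) | {hubs[m]} for m in range(spec.n_modules)
    }
    submodules_truth = {
        f"M{m}.{s}": set(submembers[(m, s)])
        for m in range(spec.n_modules)
        for s in range(spec.submodules_per_module)
    }
    for name, (m, s) in peripheral_home.items():
        modules_truth[f"M{m}"].add(name)
        submodules_truth[f"M{m}.{s}"].add(name)
    truth = PlantedTruth(
        modules=modules_truth,
        submodules=submodules_truth,
        hubs=list(hubs),
        spec=asdict(spec),
    )
    return net, ann, expr, truth


def scale_free_fixture(
    n: int,
    attachment: int,
    weight_dist: Callable[[np.random.Generator], float] | None = None,
    seed: int = 0,
) -> WeightedNetwork:
    """Preferential-attachment network with seeded random edge weights.

    ``weight_dist`` draws one weight given the generator; the default is
    uniform on [0.1, 1.0] so that no edge is entirely negligible.
    """
    if not n > attachment >= 1:
        raise ValidationError("need n > attachment >= 1")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n, attachment, seed=int(rng.integers(2**31)))
    draw = weight_dist if weight_dist is not None else (
        lambda r: float(r.uniform(0.1, 1.0))
    )
    return WeightedNetwork(
        ((f"n{u:03d}", f"n{v:03d}", draw(rng)) for u, v in sorted(g.edges()))
    )
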