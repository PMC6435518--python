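"""The component-GO-effect capacity network and max-flow relation scores.

The three node classes are connected component → GO term (capacity = the
component's term weight), GO term ↔ GO term (two antiparallel arcs holding
the GOI similarity, the standard undirected-to-directed flow reduction) and
GO term → effect (capacity = the effect's term weight).  The relation score
``z_ij`` of component ``i`` and effect ``j`` is the maximum flow from ``i``
to ``j`` on the subnetwork with all other component and effect nodes
removed, so other entities can neither siphon nor relay flow.

Capacities are floats; flows are computed on integer-scaled capacities
(default scale 1e6, round-to-nearest) to keep augmenting-path methods exact
and terminating, then divided back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .enrichment import EntityTermWeights
from .goi import GoiEdge
from .io_formats import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TriModeNetwork",
    "FlowScoreMatrix",
    "assemble",
    "maxflow_score",
    "score_matrix",
    "DEFAULT_SCALE",
]

DEFAULT_SCALE = 10**6


@dataclass(frozen=True)
class TriModeNetwork:
    """A layered capacity graph over components, GO terms and effects.

    Arcs exist only as component→GO, GO↔GO (antiparallel, equal capacity)
    and GO→effect; every capacity is finite and non-negative.
    """

    components: tuple[str, ...]
    go_terms: tuple[str, ...]
    effects: tuple[str, ...]
    arcs: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        comps, gos, effs = set(self.components), set(self.go_terms), set(self.effects)
        if comps & gos or comps & effs or gos & effs:
            raise ValidationError("node classes must be disjoint")
        arcs = dict(self.arcs)
        for (u, v), cap in arcs.items():
            if not np.isfinite(cap) or cap < 0:
                raise ValidationError(f"arc {u}->{v}: capacity {cap} not finite/>=0")
            if u in comps and v in gos:
                continue
            if u in gos and v in effs:
                continue
            if u in gos and v in gos and u != v:
                if arcs.get((v, u)) != cap:
                    raise ValidationError(
                        f"GO-GO arc {u}->{v} lacks an equal antiparallel arc"
                    )
                continue
            raise ValidationError(f"arc {u}->{v} violates the layer structure")
        object.__setattr__(self, "arcs", arcs)

    def node_order(self) -> list[str]:
        return [*self.components, *self.go_terms, *self.effects]

    def node_mode(self, node: str) -> str:
        if node in self.components:
            return "component"
        if node in self.go_terms:
            return "go"
        if node in self.effects:
            return "effect"
        raise KeyError(node)


def assemble(
    component_weights: Sequence[EntityTermWeights],
    goi_edges: Sequence[GoiEdge],
    effect_weights: Sequence[EntityTermWeights],
    goi_capacity: str = "coefficient",
) -> TriModeNetwork:
    """Merge the three layers into one capacity network.

    GO nodes are the union of term ids seen in any layer; identical ids are
    merged into a single node.  ``goi_capacity`` selects the GO↔GO arc
    capacity: the overlap ``coefficient`` (default, on the same [0,1] scale
    as the entity weights), the raw overlap ``count``, or
    ``normalized-count`` (count / max count).  GO nodes that are unreachable
    from every component and also cannot reach any effect are pruned.
    """
    if not component_weights or not effect_weights:
        raise ValidationError("need at least one component and one effect layer")
    if goi_capacity not in {"coefficient", "count", "normalized-count"}:
        raise ValidationError(f"unknown goi_capacity {goi_capacity!r}")

    components = tuple(sorted(w.entity for w in component_weights))
    effects = tuple(sorted(w.entity for w in effect_weights))
    if len(set(components)) != len(components) or len(set(effects)) != len(effects):
        raise ValidationError("duplicate entity names within a layer")

    go: set[str] = set()
    for w in (*component_weights, *effect_weights):
        go.update(w.weights)
    for e in goi_edges:
        go.update((e.term_a, e.term_b))

    max_count = max((e.overlap_count for e in goi_edges), default=0)

    def goi_cap(edge: GoiEdge) -> float:
        if goi_capacity == "coefficient":
            return edge.coefficient
        if goi_capacity == "count":
            return float(edge.overlap_count)
        return edge.overlap_count / max_count if max_count else 0.0

    arcs: dict[tuple[str, str], float] = {}
    for w in component_weights:
        for term, cap in w.weights.items():
            arcs[(w.entity, term)] = float(cap)
    for w in effect_weights:
        for term, cap in w.weights.items():
            arcs[(term, w.entity)] = float(cap)
    for e in goi_edges:
        cap = goi_cap(e)
        arcs[(e.term_a, e.term_b)] = cap
        arcs[(e.term_b, e.term_a)] = cap

    # prune GO nodes with no flow role: unreachable from all components AND
    # unable to reach any effect
    fwd = _reach({(u, v) for (u, v) in arcs if arcs[(u, v)] > 0}, set(components), go)
    bwd = _reach(
        {(v, u) for (u, v) in arcs if arcs[(u, v)] > 0}, set(effects), go
    )
    keep = {g for g in go if g in fwd or g in bwd}
    dropped = sorted(go - keep)
    if dropped:
        logger.info("pruned %d unconnected GO node(s): %s", len(dropped), dropped[:10])
    arcs = {
        (u, v): c
        for (u, v), c in arcs.items()
        if (u not in go or u in keep) and (v not in go or v in keep)
    }
    return TriModeNetwork(
        components=components,
        go_terms=tuple(sorted(keep)),
        effects=effects,
        arcs=arcs,
    )


def _reach(arcs: set[tuple[str, str]], sources: set[str], go: set[str]) -> set[str]:
    adj: dict[str, list[str]] = {}
    for u, v in arcs:
        adj.setdefault(u, []).append(v)
    seen: set[str] = set()
    stack = list(sources)
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v in go and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _flow_graph(
    net: TriModeNetwork, component: str, effect: str, scale: int
) -> nx.DiGraph:
    graph = nx.DiGraph()
    graph.add_node(component)
    graph.add_nodes_from(net.go_terms)
    graph.add_node(effect)
    excluded = (set(net.components) | set(net.effects)) - {component, effect}
    for (u, v) in sorted(net.arcs):
        if u in excluded or v in excluded:
            continue
        graph.add_edge(u, v, capacity=int(round(net.arcs[(u, v)] * scale)))
    return graph


def maxflow_score(
    net: TriModeNetwork,
    component: str,
    effect: str,
    scale: int = DEFAULT_SCALE,
) -> float:
    """Maximum flow from one component to one effect, in isolation.

    All other component and effect nodes are removed before solving, so the
    score measures the pair's own relation through the GO layer.  Returns 0
    when no path exists.
    """
    if component not in net.components:
        raise ValidationError(f"unknown component {component!r}")
    if effect not in net.effects:
        raise ValidationError(f"unknown effect {effect!r}")
    graph = _flow_graph(net, component, effect, scale)
    value = nx.maximum_flow_value(graph, component, effect)
    return value / scale


@dataclass(frozen=True)
class FlowScoreMatrix:
    """The m×n matrix of pairwise max-flow relation scores ``z_ij``."""

    components: tuple[str, ...]
    effects: tuple[str, ...]
    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.shape != (len(self.components), len(self.effects)):
            raise ValidationError(
                f"z shape {z.shape} does not match labels "
                f"({len(self.components)}x{len(self.effects)})"
            )
        if not np.all(np.isfinite(z)) or np.any(z < 0):
            raise ValidationError("z entries must be finite and >= 0")
        z.setflags(write=False)
        object.__setattr__(self, "z", z)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.z, index=list(self.components), columns=list(self.effects)
        )


def score_matrix(net: TriModeNetwork, scale: int = DEFAULT_SCALE) -> FlowScoreMatrix:
    """All pairwise max-flow scores, rows = components, columns = effects."""
    z = np.zeros((len(net.components), len(net.effects)))
    for i, comp in enumerate(net.components):
        for j, eff in enumerate(net.effects):
            z[i, j] = maxflow_score(net, comp, eff, scale=scale)
    return FlowScoreMatrix(components=net.components, effects=net.effects, z=z)
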