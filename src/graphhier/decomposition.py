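"""Hierarchical decomposition of directed graphs.

A *source subgraph* receives no edges from the rest of the graph; a minimal
one (minimal under inclusion) is strongly connected, and dually for sinks.
The minimal source subgraphs are exactly the strongly-connected components
that are sources of the condensation DAG, which is how they are computed
here (linear time), rather than by subgraph enumeration.

Removing the edges internal to all minimal source subgraphs (and deleting
vertices left isolated) yields the simply forward influenced subgraph F_f;
removing sink-internal edges gives F_b; removing both gives the core C.
The collection {Gamma_1..Gamma_l, C, Delta_1..Delta_m} is the hierarchical
decomposition; it is trivial exactly when the graph is strongly connected.
Vertices inside some minimal source (sink) subgraph are the forward
(backward) *influencers* — the vertices whose colours survive the influence
dynamics — and all others are forward (backward) *influenced*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .graph_core import WeightedDigraph, transpose

__all__ = [
    "Subgraph",
    "Decomposition",
    "sources_and_sinks",
    "minimal_source_subgraphs",
    "minimal_sink_subgraphs",
    "is_simply_forward_influenced",
    "is_simply_backward_influenced",
    "hierarchical_decomposition",
    "classify_vertices",
]


@dataclass(frozen=True)
class Subgraph:
    """A vertex set together with the graph's edges internal to it."""

    vertices: frozenset
    edges: tuple  # (tail, head, weight) records with both endpoints inside


@dataclass(frozen=True)
class Decomposition:
    """Hierarchical decomposition {Gamma_1.., C, Delta_1..} plus F_f, F_b."""

    source_subgraphs: tuple[Subgraph, ...]
    sink_subgraphs: tuple[Subgraph, ...]
    forward_influenced_subgraph: Subgraph
    backward_influenced_subgraph: Subgraph
    core: Subgraph
    trivial: bool


def _internal_edges(graph: WeightedDigraph, vertices: frozenset) -> tuple:
    return tuple(
        (u, v, w)
        for u, v, w in graph.edge_records()
        if u in vertices and v in vertices
    )


def sources_and_sinks(graph: WeightedDigraph) -> tuple[set, set]:
    """(So(G), Si(G)): vertices with zero in-degree / zero out-degree."""
    has_in = {graph.vertex_ids[h] for h in graph.heads}
    has_out = {graph.vertex_ids[t] for t in graph.tails}
    all_v = set(graph.vertex_ids)
    return all_v - has_in, all_v - has_out


def _condensation_subgraphs(graph: WeightedDigraph, kind: str) -> list[Subgraph]:
    nxg = graph.to_networkx()
    cond = nx.condensation(nxg)
    degree = cond.in_degree if kind == "source" else cond.out_degree
    members = []
    for node, data in cond.nodes(data=True):
        if degree(node) == 0:
            members.append(frozenset(data["members"]))
    # stable order: by first appearance of the earliest member vertex
    pos = {v: i for i, v in enumerate(graph.vertex_ids)}
    members.sort(key=lambda s: min(pos[v] for v in s))
    return [Subgraph(vertices=s, edges=_internal_edges(graph, s)) for s in members]


def minimal_source_subgraphs(graph: WeightedDigraph) -> list[Subgraph]:
    """Minimal source subgraphs Gamma_i (strongly connected by construction)."""
    if graph.n_vertices > 1 and not graph.is_weakly_connected():
        warnings.warn(
            "graph is not weakly connected: minimal source/sink subgraphs "
            "are reported per weakly connected component",
            stacklevel=2,
        )
    return _condensation_subgraphs(graph, "source")


def minimal_sink_subgraphs(graph: WeightedDigraph) -> list[Subgraph]:
    """Minimal sink subgraphs Delta_j (minimal source subgraphs of G^T)."""
    return _condensation_subgraphs(graph, "sink")


def is_simply_forward_influenced(graph: WeightedDigraph) -> bool:
    """True iff sources exist, non-sources exist, and every non-source is
    reachable from some source (the graphs on which trophic levels exist)."""
    sources, _ = sources_and_sinks(graph)
    non_sources = set(graph.vertex_ids) - sources
    if not sources or not non_sources:
        return False
    nxg = graph.to_networkx()
    reached = set(sources)
    for layer in nx.bfs_layers(nxg, sources=list(sources)):
        reached.update(layer)
    return non_sources <= reached


def is_simply_backward_influenced(graph: WeightedDigraph) -> bool:
    return is_simply_forward_influenced(transpose(graph))


def _remove_internal(graph: WeightedDigraph, blocks: list[Subgraph]) -> Subgraph:
    drop = set()
    for block in blocks:
        drop.update((u, v) for u, v, _ in block.edges)
    kept = tuple(
        (u, v, w) for u, v, w in graph.edge_records() if (u, v) not in drop
    )
    touched = frozenset(x for u, v, _ in kept for x in (u, v))
    return Subgraph(vertices=touched, edges=kept)


def hierarchical_decomposition(graph: WeightedDigraph) -> Decomposition:
    """Compute {Gamma_i}, {Delta_j}, F_f, F_b and the core C.

    Isolated input vertices form their own (edgeless) trivial source-and-sink
    subgraphs and never belong to F_f, F_b or C.
    """
    gammas = minimal_source_subgraphs(graph)
    deltas = minimal_sink_subgraphs(graph)
    f_f = _remove_internal(graph, gammas)
    f_b = _remove_internal(graph, deltas)
    core = _remove_internal(graph, gammas + deltas)
    trivial = (
        len(gammas) == 1
        and len(deltas) == 1
        and gammas[0].vertices == frozenset(graph.vertex_ids)
        and deltas[0].vertices == frozenset(graph.vertex_ids)
    )
    return Decomposition(
        source_subgraphs=tuple(gammas),
        sink_subgraphs=tuple(deltas),
        forward_influenced_subgraph=f_f,
        backward_influenced_subgraph=f_b,
        core=core,
        trivial=trivial,
    )


def classify_vertices(
    graph: WeightedDigraph, decomposition: Decomposition | None = None
) -> dict:
    """Label each vertex forward/backward influencer or influenced.

    Returns ``{vertex: {"forward": "influencer"|"influenced",
    "backward": ...}}``.  A vertex is a forward influencer iff it lies in
    some minimal source subgraph; the zero/positive pattern of the influence
    centralities matches this classification on weakly connected graphs.
    """
    if decomposition is None:
        decomposition = hierarchical_decomposition(graph)
    fwd = set().union(*(s.vertices for s in decomposition.source_subgraphs))
    bwd = set().union(*(s.vertices for s in decomposition.sink_subgraphs))
    return {
        v: {
            "forward": "influencer" if v in fwd else "influenced",
            "backward": "influencer" if v in bwd else "influenced",
        }
        for v in graph.vertex_ids
    }
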