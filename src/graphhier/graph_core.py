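"""Weighted simple directed graphs and their degree / Laplacian objects.

The whole package operates on one canonical container, :class:`WeightedDigraph`:
a simple (no self-loops, no parallel edges) directed graph with strictly
positive edge weights and a stable vertex order.  All vector-valued results
elsewhere in the package (levels, centralities, degree vectors) are indexed by
that order, which is the order of first appearance in the input.

Notation used throughout the package: ``A`` is the weighted adjacency matrix
with ``A[i, j] > 0`` iff there is an edge i -> j; ``d`` and ``delta`` are the
weighted in- and out-degree vectors; ``L = diag(d) - A`` is the in-degree
Laplacian, ``M = L.T`` its transpose, and ``Lambda = diag(delta) - A`` the
out-degree Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "GraphValidationError",
    "WeightedDigraph",
    "DegreeVectors",
    "LaplacianPair",
    "build_graph",
    "transpose",
    "degree_vectors",
    "laplacians",
]


class GraphValidationError(ValueError):
    """Raised when edge records violate the simple-graph contract."""


@dataclass(frozen=True)
class WeightedDigraph:
    """A simple, positively weighted directed graph with ordered vertices.

    Attributes
    ----------
    vertex_ids
        Vertex labels in stable (first-appearance) order.  Every vector
        produced by this package is indexed in this order.
    tails, heads
        Integer edge endpoint indices into ``vertex_ids``.
    weights
        Strictly positive edge weights, aligned with ``tails``/``heads``.
    undirected_origin
        True when the graph was expanded from an undirected edge list; the
        hierarchy code uses this to warn that combined levels vanish.
    """

    vertex_ids: tuple
    tails: np.ndarray
    heads: np.ndarray
    weights: np.ndarray
    undirected_origin: bool = False
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self._index:
            object.__setattr__(
                self, "_index", {v: i for i, v in enumerate(self.vertex_ids)}
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def index_of(self, vertex: Hashable) -> int:
        return self._index[vertex]

    def adjacency(self) -> sp.csr_array:
        """Sparse weighted adjacency matrix A with A[i, j] = w(i -> j)."""
        n = self.n_vertices
        return sp.csr_array(
            (self.weights, (self.tails, self.heads)), shape=(n, n), dtype=float
        )

    def edge_records(self) -> list[tuple]:
        """Edges as (tail_label, head_label, weight) in storage order."""
        ids = self.vertex_ids
        return [
            (ids[t], ids[h], float(w))
            for t, h, w in zip(self.tails, self.heads, self.weights)
        ]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertex_ids)
        g.add_weighted_edges_from(self.edge_records())
        return g

    def is_weakly_connected(self) -> bool:
        if self.n_vertices <= 1:
            return True
        return nx.is_weakly_connected(self.to_networkx())

    def is_strongly_connected(self) -> bool:
        if self.n_vertices <= 1:
            return True
        return nx.is_strongly_connected(self.to_networkx())


@dataclass(frozen=True)
class DegreeVectors:
    """Weighted in-degree ``d`` and out-degree ``delta``, vertex-ordered."""

    d: np.ndarray
    delta: np.ndarray


@dataclass(frozen=True)
class LaplacianPair:
    """Sparse Laplacians: ``L = diag(d) - A``, ``M = L.T``, ``Lambda = diag(delta) - A``."""

    L: sp.csr_array
    M: sp.csr_array
    Lambda: sp.csr_array


def build_graph(
    edge_records: Iterable[tuple],
    vertices: Sequence[Hashable] | None = None,
    undirected: bool = False,
) -> WeightedDigraph:
    """Build a :class:`WeightedDigraph` from (tail, head[, weight]) records.

    Weights default to 1.  Vertex order is first appearance (tails before
    heads within a record); isolated vertices may be declared via *vertices*,
    which also fixes the order of any labels it lists.

    With ``undirected=True`` each record (u, v, w) is expanded to the directed
    pair u -> v and v -> u of equal weight.

    Raises
    ------
    GraphValidationError
        On self-loops, non-positive weights, or duplicate ordered pairs
        (the graph is required to be simple; duplicates are an error rather
        than being weight-summed).
    """
    order: dict = {}
    if vertices is not None:
        for v in vertices:
            if v in order:
                raise GraphValidationError(f"duplicate vertex label {v!r}")
            order[v] = len(order)

    seen: set[tuple] = set()
    tails: list[int] = []
    heads: list[int] = []
    weights: list[float] = []

    def add_edge(u, v, w):
        if u == v:
            raise GraphValidationError(
                f"self-loop {u!r} -> {v!r}: simple graphs have no self-loops"
            )
        w = float(w)
        if not w > 0:
            raise GraphValidationError(
                f"edge {u!r} -> {v!r} has non-positive weight {w}"
            )
        if (u, v) in seen:
            raise GraphValidationError(f"duplicate edge {u!r} -> {v!r}")
        seen.add((u, v))
        for x in (u, v):
            if x not in order:
                order[x] = len(order)
        tails.append(order[u])
        heads.append(order[v])
        weights.append(w)

    for rec in edge_records:
        if len(rec) == 2:
            u, v = rec
            w = 1.0
        elif len(rec) == 3:
            u, v, w = rec
        else:
            raise GraphValidationError(f"malformed edge record {rec!r}")
        add_edge(u, v, w)
        if undirected:
            add_edge(v, u, w)

    return WeightedDigraph(
        vertex_ids=tuple(order),
        tails=np.asarray(tails, dtype=np.intp),
        heads=np.asarray(heads, dtype=np.intp),
        weights=np.asarray(weights, dtype=float),
        undirected_origin=undirected,
    )


def from_networkx(g: nx.DiGraph) -> WeightedDigraph:
    """Convert a networkx DiGraph (``weight`` edge attribute, default 1)."""
    records = [
        (u, v, data.get("weight", 1.0)) for u, v, data in g.edges(data=True)
    ]
    return build_graph(records, vertices=list(g.nodes))


def transpose(graph: WeightedDigraph) -> WeightedDigraph:
    """Reverse every edge, keeping weights and vertex order. An involution."""
    return WeightedDigraph(
        vertex_ids=graph.vertex_ids,
        tails=graph.heads,
        heads=graph.tails,
        weights=graph.weights,
        undirected_origin=graph.undirected_origin,
    )


def degree_vectors(graph: WeightedDigraph) -> DegreeVectors:
    """Weighted in/out degree vectors; both sum to the total edge weight."""
    n = graph.n_vertices
    d = np.bincount(graph.heads, weights=graph.weights, minlength=n)
    delta = np.bincount(graph.tails, weights=graph.weights, minlength=n)
    return DegreeVectors(d=d, delta=delta)


def laplacians(graph: WeightedDigraph) -> LaplacianPair:
    """Sparse in-degree and out-degree Laplacians (and M = L.T)."""
    A = graph.adjacency()
    deg = degree_vectors(graph)
    L = sp.csr_array(sp.diags_array(deg.d) - A)
    Lambda = sp.csr_array(sp.diags_array(deg.delta) - A)
    return LaplacianPair(L=L, M=sp.csr_array(L.T), Lambda=Lambda)
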