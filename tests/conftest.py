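"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own computational paths:
levels are recomputed with a dense Moore-Penrose pseudoinverse, and minimal
source subgraphs by brute-force enumeration of all vertex subsets.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from graphhier import build_graph, fixtures
from graphhier.graph_core import WeightedDigraph


@pytest.fixture(scope="session")
def toy() -> dict:
    return fixtures()


# ---------------------------------------------------------------- oracles


def dense_adjacency(graph: WeightedDigraph) -> np.ndarray:
    return graph.adjacency().toarray()


def oracle_forward_levels(graph: WeightedDigraph) -> np.ndarray:
    """g = M^+ d: the dense SVD-based minimal-norm least-squares solution.

    ``np.linalg.lstsq`` applies the Moore-Penrose pseudoinverse through the
    SVD without ever forming M^+ explicitly; forming ``pinv(M)`` and
    multiplying is numerically unstable on ill-conditioned Laplacians.
    """
    A = dense_adjacency(graph)
    d = A.sum(axis=0)
    M = (np.diag(d) - A).T
    return np.linalg.lstsq(M, d, rcond=None)[0]


def oracle_backward_levels(graph: WeightedDigraph) -> np.ndarray:
    A = dense_adjacency(graph)
    delta = A.sum(axis=1)
    Lam = np.diag(delta) - A
    return np.linalg.lstsq(Lam, delta, rcond=None)[0]


def brute_force_minimal_source_sets(graph: WeightedDigraph) -> set[frozenset]:
    """Inclusion-minimal non-empty vertex sets with no incoming edge."""
    vertices = list(graph.vertex_ids)
    edges = [(u, v) for u, v, _ in graph.edge_records()]
    closed = []
    for r in range(1, len(vertices) + 1):
        for combo in itertools.combinations(vertices, r):
            s = set(combo)
            if not any(u not in s and v in s for u, v in edges):
                closed.append(frozenset(s))
    return {
        s
        for s in closed
        if not any(t < s for t in closed)
    }


def random_digraph(
    rng: np.random.Generator,
    n_max: int = 8,
    weighted: bool = True,
    ensure_edge: bool = True,
) -> WeightedDigraph:
    """A random simple digraph with optional random positive weights."""
    n = int(rng.integers(2, n_max + 1))
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    p = rng.uniform(0.15, 0.6)
    chosen = [pair for pair in pairs if rng.random() < p]
    if ensure_edge and not chosen:
        chosen = [pairs[int(rng.integers(len(pairs)))]]
    records = [
        (u, v, float(rng.uniform(0.2, 3.0)) if weighted else 1.0)
        for u, v in chosen
    ]
    return build_graph(records, vertices=range(n))


def all_digraphs(n: int):
    """Every labelled simple digraph on n vertices (including edgeless)."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for mask in range(1 << len(pairs)):
        records = [
            (u, v, 1.0) for k, (u, v) in enumerate(pairs) if mask >> k & 1
        ]
        yield build_graph(records, vertices=range(n))
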