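"""Hierarchical levels, democracy coefficients, incoherence and influence centrality.

The forward hierarchical level vector ``g`` generalises trophic levels to any
simple directed graph: it is the minimal-Euclidean-norm minimiser of
``||M x - d||_2`` where ``M`` is the transposed in-degree Laplacian and ``d``
the in-degree vector, i.e. ``g = M^+ d``.  The backward levels ``gamma`` solve
the analogous out-degree problem, and the combined level is
``h = (g - gamma) / 2``.

From the per-edge level differences come the graph-level metrics: the
democracy coefficients ``eta = 1 - weighted mean`` of the differences (a
measure of feedback onto the graph's influencers) and the hierarchical
incoherence parameters ``rho = sqrt(weighted variance)`` (the generalisation
of the trophic incoherence parameter).  The per-vertex version of the
democracy coefficient is the influence centrality, which is positive exactly
on the vertices that drive the asymptotic state of the influence dynamics.

The least-squares problems are solved iteratively (scipy's LSMR), which forms
the pseudoinverse-vector product without ever materialising the pseudoinverse;
cost is essentially linear in the number of edges for sparse graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsmr

from .graph_core import (
    WeightedDigraph,
    degree_vectors,
    laplacians,
    transpose,
)

__all__ = [
    "HierarchyLevels",
    "EdgeDifferences",
    "HierarchyMetrics",
    "InfluenceCentralities",
    "forward_levels",
    "backward_levels",
    "hierarchical_levels",
    "edge_differences",
    "democracy_coefficients",
    "incoherence_parameters",
    "hierarchy_metrics",
    "influence_centrality_forward",
    "influence_centrality_backward",
    "influence_centralities",
    "stationary_from_centrality",
]

#: absolute tolerance below which a centrality is classified as zero
ZERO_TOL = 1e-8

_SOLVER_TOL = 1e-10


@dataclass(frozen=True)
class HierarchyLevels:
    """Per-vertex forward (g), backward (gamma) and combined (h) levels."""

    g: np.ndarray
    gamma: np.ndarray
    h: np.ndarray


@dataclass(frozen=True)
class EdgeDifferences:
    """Per-edge hierarchical level differences.

    ``forward_diff[k] = g[head_k] - g[tail_k]`` and
    ``backward_diff[k] = gamma[tail_k] - gamma[head_k]``, one entry per edge,
    aligned with the graph's edge storage order.
    """

    tails: np.ndarray
    heads: np.ndarray
    weights: np.ndarray
    forward_diff: np.ndarray
    backward_diff: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class HierarchyMetrics:
    """Graph-level summary: democracy coefficients and incoherence parameters."""

    eta_f: float
    eta_b: float
    rho_f: float
    rho_b: float


@dataclass(frozen=True)
class InfluenceCentralities:
    """Forward (e) and backward (epsilon) influence centrality per vertex."""

    e: np.ndarray
    epsilon: np.ndarray


def _minimal_norm_lstsq(M: sp.csr_array, b: np.ndarray) -> np.ndarray:
    # LSMR started from zero converges to the minimal-norm least-squares
    # solution.  One iterative-refinement pass (also started from zero, so
    # the correction stays in the row space and minimality is preserved)
    # buys the extra digits needed for the 1e-8 identities downstream.
    n = M.shape[0]
    if n == 0:
        return np.zeros(0)
    maxiter = max(10 * n, 100)
    x = lsmr(M, b, atol=_SOLVER_TOL, btol=_SOLVER_TOL, maxiter=maxiter)[0]
    dx = lsmr(M, b - M @ x, atol=_SOLVER_TOL, btol=_SOLVER_TOL, maxiter=maxiter)[0]
    return x + dx


def _warn_if_special(graph: WeightedDigraph) -> None:
    if graph.undirected_origin:
        warnings.warn(
            "graph was expanded from an undirected edge list: forward and "
            "backward levels coincide, so the combined level h is "
            "identically 0; use the forward quantities",
            stacklevel=3,
        )
    elif graph.n_edges and not graph.is_weakly_connected():
        warnings.warn(
            "graph is not weakly connected: levels and metrics are computed "
            "on the full graph, but the sign/zero guarantees for democracy "
            "coefficients and influence centralities hold per weakly "
            "connected component",
            stacklevel=3,
        )


def forward_levels(graph: WeightedDigraph) -> np.ndarray:
    """Forward hierarchical levels g = M^+ d (minimal-norm least squares)."""
    if graph.n_vertices == 0:
        raise ValueError("graph has no vertices")
    lap = laplacians(graph)
    deg = degree_vectors(graph)
    return _minimal_norm_lstsq(lap.M, deg.d)


def backward_levels(graph: WeightedDigraph) -> np.ndarray:
    """Backward hierarchical levels gamma = Lambda^+ delta.

    Equal to the forward levels of the transpose graph.
    """
    if graph.n_vertices == 0:
        raise ValueError("graph has no vertices")
    lap = laplacians(graph)
    deg = degree_vectors(graph)
    return _minimal_norm_lstsq(sp.csr_array(lap.Lambda), deg.delta)


def hierarchical_levels(graph: WeightedDigraph) -> HierarchyLevels:
    """Bundle g, gamma and the combined level h = (g - gamma)/2."""
    _warn_if_special(graph)
    g = forward_levels(graph)
    gamma = backward_levels(graph)
    return HierarchyLevels(g=g, gamma=gamma, h=(g - gamma) / 2.0)


def edge_differences(
    graph: WeightedDigraph, levels: HierarchyLevels | None = None
) -> EdgeDifferences:
    """Per-edge forward/backward hierarchical differences (FHD / BHD)."""
    if levels is None:
        levels = hierarchical_levels(graph)
    return EdgeDifferences(
        tails=graph.tails,
        heads=graph.heads,
        weights=graph.weights,
        forward_diff=levels.g[graph.heads] - levels.g[graph.tails],
        backward_diff=levels.gamma[graph.tails] - levels.gamma[graph.heads],
    )


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(values, weights=weights))


def _weighted_std(values: np.ndarray, weights: np.ndarray) -> float:
    # population variance with weights normalised by the total edge weight
    mean = np.average(values, weights=weights)
    return float(np.sqrt(np.average((values - mean) ** 2, weights=weights)))


def democracy_coefficients(diffs: EdgeDifferences) -> tuple[float, float]:
    """(eta_f, eta_b): 1 minus the weight-averaged hierarchical differences."""
    if diffs.n_edges == 0:
        raise ValueError("democracy coefficients are undefined on an edgeless graph")
    return (
        1.0 - _weighted_mean(diffs.forward_diff, diffs.weights),
        1.0 - _weighted_mean(diffs.backward_diff, diffs.weights),
    )


def incoherence_parameters(diffs: EdgeDifferences) -> tuple[float, float]:
    """(rho_f, rho_b): weighted standard deviations of the differences."""
    if diffs.n_edges == 0:
        raise ValueError("incoherence parameters are undefined on an edgeless graph")
    return (
        _weighted_std(diffs.forward_diff, diffs.weights),
        _weighted_std(diffs.backward_diff, diffs.weights),
    )


def hierarchy_metrics(
    graph: WeightedDigraph, levels: HierarchyLevels | None = None
) -> HierarchyMetrics:
    """Democracy coefficients and incoherence parameters of the graph."""
    diffs = edge_differences(graph, levels)
    eta_f, eta_b = democracy_coefficients(diffs)
    rho_f, rho_b = incoherence_parameters(diffs)
    return HierarchyMetrics(eta_f=eta_f, eta_b=eta_b, rho_f=rho_f, rho_b=rho_b)


def influence_centrality_forward(
    graph: WeightedDigraph, levels: HierarchyLevels | None = None
) -> np.ndarray:
    """Forward influence centrality e.

    ``e[j] = 1 - weighted mean of (g[j] - g[i])`` over the in-edges i -> j;
    vertices with no in-edges get ``e[j] = 1`` (the mean of an empty set is
    taken to be 0).  Positive exactly on forward influencers, and satisfies
    the identity ``M g = d * (1 - e)`` elementwise.
    """
    if levels is None:
        levels = hierarchical_levels(graph)
    n = graph.n_vertices
    g = levels.g
    num = np.bincount(
        graph.heads,
        weights=graph.weights * (g[graph.heads] - g[graph.tails]),
        minlength=n,
    )
    den = np.bincount(graph.heads, weights=graph.weights, minlength=n)
    mean = np.divide(num, den, out=np.zeros(n), where=den > 0)
    return 1.0 - mean


def influence_centrality_backward(
    graph: WeightedDigraph, levels: HierarchyLevels | None = None
) -> np.ndarray:
    """Backward influence centrality epsilon.

    ``epsilon[j] = 1 - weighted mean of (gamma[j] - gamma[k])`` over the
    out-edges j -> k (empty set -> 1).  Equals the forward influence
    centrality of the transpose graph and is positive exactly on backward
    influencers.
    """
    if levels is None:
        levels = hierarchical_levels(graph)
    n = graph.n_vertices
    gamma = levels.gamma
    num = np.bincount(
        graph.tails,
        weights=graph.weights * (gamma[graph.tails] - gamma[graph.heads]),
        minlength=n,
    )
    den = np.bincount(graph.tails, weights=graph.weights, minlength=n)
    mean = np.divide(num, den, out=np.zeros(n), where=den > 0)
    return 1.0 - mean


def influence_centralities(
    graph: WeightedDigraph, levels: HierarchyLevels | None = None
) -> InfluenceCentralities:
    if levels is None:
        levels = hierarchical_levels(graph)
    return InfluenceCentralities(
        e=influence_centrality_forward(graph, levels),
        epsilon=influence_centrality_backward(graph, levels),
    )


def stationary_from_centrality(
    graph: WeightedDigraph, epsilon: np.ndarray | None = None
) -> np.ndarray:
    """Random-walk stationary distribution from backward influence centrality.

    On a strongly connected graph the stationary distribution of the
    weight-proportional out-edge random walk is
    ``pi = diag(delta)^2 epsilon / || diag(delta)^2 epsilon ||_1``.
    """
    if not graph.is_strongly_connected():
        raise ValueError(
            "stationary distribution from centrality requires a strongly "
            "connected graph"
        )
    if epsilon is None:
        epsilon = influence_centrality_backward(graph)
    delta = degree_vectors(graph).delta
    unnorm = delta**2 * epsilon
    return unnorm / unnorm.sum()
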