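"""Influence (colour-copying) dynamics and random-walk stationary distributions.

Forward influence dynamics: every vertex holds a colour; at each step, vertex
i picks itself with probability 1/(1 + d_i) or in-neighbour j with probability
a_ji/(1 + d_i) (its own weight is always 1), and all vertices simultaneously
adopt their pick's colour.  Source vertices keep their colour forever, and in
the long run the surviving colours are those of the minimal source subgraphs.
Backward dynamics is the same process on the transpose graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph_core import WeightedDigraph, degree_vectors, transpose

__all__ = [
    "ColourState",
    "InfluenceRun",
    "influence_step",
    "influence_run",
    "stationary_distribution",
]


@dataclass(frozen=True)
class ColourState:
    """Integer colour label per vertex at a given time step."""

    colours: np.ndarray
    time: int = 0

    def n_colours(self) -> int:
        return len(np.unique(self.colours))


@dataclass(frozen=True)
class InfluenceRun:
    """Trajectory summary of an influence-dynamics run."""

    initial: ColourState
    final: ColourState
    steps_taken: int
    absorbed: bool
    surviving_colours: frozenset


def _incoming_structure(graph: WeightedDigraph):
    """CSC adjacency so that column i lists the in-edges of vertex i."""
    A = sp.csc_array(graph.adjacency())
    d = degree_vectors(graph).d
    return A, d


def influence_step(
    graph: WeightedDigraph,
    state: ColourState,
    rng: np.random.Generator,
    direction: str = "forward",
) -> ColourState:
    """One synchronous update of the influence dynamics.

    Vertex i keeps its colour with probability 1/(1 + d_i) and copies
    in-neighbour j with probability a_ji/(1 + d_i).  ``direction="backward"``
    runs the same rule on the transpose graph.
    """
    if direction == "backward":
        graph = transpose(graph)
    elif direction != "forward":
        raise ValueError(f"unknown direction {direction!r}")
    A, d = _incoming_structure(graph)
    old = state.colours
    new = old.copy()
    draws = rng.random(graph.n_vertices) * (1.0 + d)
    for i in np.nonzero(draws >= 1.0)[0]:
        lo, hi = A.indptr[i], A.indptr[i + 1]
        neigh = A.indices[lo:hi]
        cum = np.cumsum(A.data[lo:hi])
        j = neigh[np.searchsorted(cum, draws[i] - 1.0, side="right")]
        new[i] = old[j]
    return ColourState(colours=new, time=state.time + 1)


def _is_absorbing(A: sp.csc_array, colours: np.ndarray) -> bool:
    # a state is a fixed point with certainty iff every vertex's closed
    # in-neighbourhood is monochromatic
    for i in range(len(colours)):
        neigh = A.indices[A.indptr[i] : A.indptr[i + 1]]
        if neigh.size and np.any(colours[neigh] != colours[i]):
            return False
    return True


def influence_run(
    graph: WeightedDigraph,
    init: ColourState | np.ndarray,
    max_steps: int,
    rng: np.random.Generator,
    direction: str = "forward",
) -> InfluenceRun:
    """Iterate :func:`influence_step` until absorption or ``max_steps``.

    Absorption is detected exactly: the state can never change again iff
    every vertex's in-neighbours (out-neighbours for backward dynamics)
    share its colour.  The distinct-colour count is non-increasing along the
    trajectory, and the surviving colours always originate in the minimal
    source (sink) subgraphs.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if isinstance(init, np.ndarray):
        init = ColourState(colours=np.asarray(init), time=0)
    work = transpose(graph) if direction == "backward" else graph
    A, _ = _incoming_structure(work)
    state = init
    absorbed = _is_absorbing(A, state.colours)
    steps = 0
    while not absorbed and steps < max_steps:
        state = influence_step(graph, state, rng, direction=direction)
        steps += 1
        absorbed = _is_absorbing(A, state.colours)
    return InfluenceRun(
        initial=init,
        final=state,
        steps_taken=steps,
        absorbed=absorbed,
        surviving_colours=frozenset(np.unique(state.colours).tolist()),
    )


def stationary_distribution(graph: WeightedDigraph) -> np.ndarray:
    """Stationary distribution of the weight-proportional out-edge random walk.

    Solves ``pi P = pi`` with ``sum(pi) = 1`` directly, where
    ``P = diag(delta)^{-1} A`` is the row-stochastic transition matrix; the
    direct solve also covers periodic chains (e.g. pure cycles).  Serves as
    the independent check of the identity
    ``pi = diag(delta)^2 epsilon / ||.||_1``.
    """
    if not graph.is_strongly_connected():
        transient = [
            v
            for v, lab in _transient_labels(graph).items()
            if lab == "transient"
        ]
        raise ValueError(
            "graph is not strongly connected; vertices with 0 backward "
            f"influence centrality are transient states: {sorted(map(str, transient))}"
        )
    delta = degree_vectors(graph).delta
    P = graph.adjacency().toarray() / delta[:, None]
    n = graph.n_vertices
    lhs = np.vstack([P.T - np.eye(n), np.ones((1, n))])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
    return pi


def _transient_labels(graph: WeightedDigraph) -> dict:
    from .decomposition import minimal_sink_subgraphs

    recurrent = set().union(
        *(s.vertices for s in minimal_sink_subgraphs(graph))
    )
    return {
        v: ("recurrent" if v in recurrent else "transient")
        for v in graph.vertex_ids
    }
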