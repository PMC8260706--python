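"""Random-graph models and fixed toy graphs.

The preferential preying model (PPM) grows food-web-like digraphs: B basal
(zero in-degree) vertices sit at tentative trophic level 1; every further
vertex attaches to one uniformly chosen existing vertex (its first prey) one
level above it, and the remaining edge budget is sampled without replacement
among absent pairs i -> j (j non-basal) with probability proportional to
``exp(-(x_j - x_i - 1)^2 / (2 T^2))`` on the tentative levels x.  The
temperature T controls hierarchy: T -> 0 gives trophically coherent, layered
webs; large T approaches a uniform (Erdos-Renyi-like) wiring.

The non-source variant (NSPPM) additionally gives every basal vertex one
incoming edge, sampled with the same Gaussian kernel aimed one level
downward, so the result has no sources at all (and hence a strictly positive
forward democracy coefficient) while staying otherwise PPM-like.

All generated graphs are unit-weighted and simple, with exactly the
requested number of edges; the same seed always reproduces the same graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import WeightedDigraph, build_graph

__all__ = [
    "PPMConfig",
    "generate_ppm",
    "generate_nsppm",
    "generate_er_directed",
    "fixtures",
]

DEFAULT_N = 500
DEFAULT_EDGES = 2500
DEFAULT_BASAL = 25


@dataclass(frozen=True)
class PPMConfig:
    """Generator parameters: N vertices, B basal, L edges, temperature T."""

    n: int = DEFAULT_N
    n_basal: int = DEFAULT_BASAL
    n_edges: int = DEFAULT_EDGES
    temperature: float = 0.5

    def __post_init__(self):
        if not 1 <= self.n_basal < self.n:
            raise ValueError("need 1 <= B < N")
        if self.n_edges < self.n - self.n_basal:
            raise ValueError("need L >= N - B so every consumer has prey")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _gumbel_top_k(
    log_w: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a size-k sample without replacement, P proportional to exp(log_w)."""
    if k == 0:
        return np.zeros(0, dtype=np.intp)
    keys = log_w + rng.gumbel(size=log_w.shape)
    return np.argpartition(-keys, k - 1)[:k]


def _grow_backbone(cfg: PPMConfig, rng: np.random.Generator):
    """Basal vertices plus the uniform-attachment spanning stage."""
    n, b = cfg.n, cfg.n_basal
    levels = np.ones(n)
    edges = []
    for v in range(b, n):
        u = int(rng.integers(0, v))
        edges.append((u, v))
        levels[v] = levels[u] + 1.0
    return levels, edges


def _preferential_edges(
    levels: np.ndarray,
    existing: list[tuple[int, int]],
    n_extra: int,
    n_basal: int,
    temperature: float,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Sample n_extra absent pairs (i -> j, j non-basal) by the Gaussian kernel."""
    n = len(levels)
    consumers = np.arange(n_basal, n)
    tails = np.repeat(np.arange(n), len(consumers))
    heads = np.tile(consumers, n)
    keep = tails != heads
    tails, heads = tails[keep], heads[keep]
    present = np.zeros((n, n), dtype=bool)
    for u, v in existing:
        present[u, v] = True
    keep = ~present[tails, heads]
    tails, heads = tails[keep], heads[keep]
    if n_extra > len(tails):
        raise ValueError(
            f"requested {n_extra} extra edges but only {len(tails)} "
            "absent (i -> non-basal j) pairs remain in a simple graph"
        )
    log_w = -((levels[heads] - levels[tails] - 1.0) ** 2) / (
        2.0 * temperature**2
    )
    pick = _gumbel_top_k(log_w, n_extra, rng)
    return list(zip(tails[pick].tolist(), heads[pick].tolist()))


def generate_ppm(cfg: PPMConfig, seed=None) -> WeightedDigraph:
    """Preferential preying model graph: exactly B sources and L unit edges.

    Every consumer is reachable from a basal vertex, so the graph is simply
    forward influenced and its forward democracy coefficient is 0.
    """
    rng = _as_rng(seed)
    levels, edges = _grow_backbone(cfg, rng)
    extra = cfg.n_edges - len(edges)
    edges += _preferential_edges(
        levels, edges, extra, cfg.n_basal, cfg.temperature, rng
    )
    return build_graph(edges, vertices=range(cfg.n))


def generate_nsppm(
    n: int = DEFAULT_N,
    n_edges: int = DEFAULT_EDGES,
    temperature: float = 0.5,
    seed=None,
    n_basal: int | None = None,
) -> WeightedDigraph:
    """Non-source preferential preying model: PPM-like but with no sources.

    Runs the PPM construction with an edge budget reduced by B, then gives
    each basal vertex one in-edge sampled with the same Gaussian kernel as
    every other edge (at low temperature the tail is another vertex near
    tentative level 1, so the feedback stays local and the forward
    influencing subgraphs stay small, matching the PPM's layering).  The
    total edge count is exactly ``n_edges``; no vertex has
    zero in-degree, so the graph is not simply forward influenced and its
    forward democracy coefficient is strictly positive.
    """
    if n_basal is None:
        n_basal = max(1, n // 20)
    if n_edges < n:
        raise ValueError("need L >= N so every vertex (incl. basal) has an in-edge")
    rng = _as_rng(seed)
    cfg = PPMConfig(
        n=n, n_basal=n_basal, n_edges=n_edges - n_basal, temperature=temperature
    )
    levels, edges = _grow_backbone(cfg, rng)
    extra = cfg.n_edges - len(edges)
    edges += _preferential_edges(
        levels, edges, extra, n_basal, temperature, rng
    )
    present = set(edges)
    for b in range(n_basal):
        tails = np.array(
            [u for u in range(n) if u != b and (u, b) not in present],
            dtype=np.intp,
        )
        log_w = -((levels[b] - levels[tails] - 1.0) ** 2) / (
            2.0 * temperature**2
        )
        pick = tails[_gumbel_top_k(log_w, 1, rng)[0]]
        edges.append((int(pick), b))
        present.add((int(pick), b))
    return build_graph(edges, vertices=range(n))


def generate_er_directed(n: int, n_edges: int, seed=None) -> WeightedDigraph:
    """Directed Erdos-Renyi G(n, L): L distinct ordered pairs, no loops."""
    max_edges = n * (n - 1)
    if n_edges > max_edges:
        raise ValueError(f"at most {max_edges} simple directed edges on {n} vertices")
    rng = _as_rng(seed)
    flat = rng.choice(max_edges, size=n_edges, replace=False)
    tails, offs = np.divmod(flat, n - 1)
    heads = offs + (offs >= tails)  # skip the diagonal
    return build_graph(list(zip(tails.tolist(), heads.tolist())), vertices=range(n))


def fixtures() -> dict[str, WeightedDigraph]:
    """Named toy graphs used throughout the docs and tests.

    chain3
        1 -> 2 -> 3, unit weights; the maximally hierarchical example.
    weighted_cycle3
        3-cycle with w(3 -> 1) = 1/2 and unit weights elsewhere.
    cycle3_plus_tail
        unit 3-cycle 1 -> 2 -> 3 -> 1 plus the edge 3 -> 4.
    unit_cycle3 / unit_cycle4
        balanced unit-weight directed cycles.
    two_cycle_weighted
        2-cycle with w(1 -> 2) = 1, w(2 -> 1) = 2.
    g5
        1 <-> 2 -> 3 -> 4 <-> 5: two 2-cycle end caps joined by a path; the
        standard decomposition example (source {1,2}, sink {4,5}).
    """
    return {
        "chain3": build_graph([(1, 2, 1), (2, 3, 1)]),
        "weighted_cycle3": build_graph([(1, 2, 1), (2, 3, 1), (3, 1, 0.5)]),
        "cycle3_plus_tail": build_graph(
            [(1, 2, 1), (2, 3, 1), (3, 1, 1), (3, 4, 1)]
        ),
        "unit_cycle3": build_graph([(1, 2, 1), (2, 3, 1), (3, 1, 1)]),
        "unit_cycle4": build_graph(
            [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 1, 1)]
        ),
        "two_cycle_weighted": build_graph([(1, 2, 1), (2, 1, 2)]),
        "g5": build_graph(
            [
                (1, 2, 1),
                (2, 1, 1),
                (2, 3, 1),
                (3, 4, 1),
                (4, 5, 1),
                (5, 4, 1),
            ]
        ),
    }
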