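"""SIS contagion dynamics on directed graphs and the incidence experiment.

The epidemic rule: vertex i is infected at time t+1 with probability
``f_i(t) ** alpha`` where ``f_i(t)`` is the fraction of i's in-neighbours
infected at time t and ``alpha > 0`` controls the infection rate (smaller
alpha = easier infection).  The t+1 state is resampled purely from the
in-neighbourhood — a vertex's own state neither protects nor predisposes it —
which is what makes the model susceptible-infected-susceptible.  Vertices
with no in-neighbours have f = 0 and can never be (re)infected after t = 0.

The incidence experiment couples this to the graph-hierarchy machinery: for
ensembles of NSPPM graphs across a temperature grid, it seeds the epidemic at
the vertices with the lowest combined hierarchical level h, measures the
incidence (fraction of vertices ever infected), and relates it to the forward
hierarchical incoherence rho_f, stratified by the forward democracy
coefficient.  Graphs with a democracy coefficient below ``threshold`` have
small forward-influencing subgraphs which, once seeded, stay infected
forever, so those runs can only end at full incidence or by hitting the
horizon — never by extinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .generators import generate_nsppm
from .graph_core import WeightedDigraph, degree_vectors
from .hierarchy import HierarchyLevels, hierarchical_levels, hierarchy_metrics

__all__ = [
    "SISConfig",
    "SISResult",
    "sis_step",
    "sis_run",
    "ExperimentConfig",
    "incidence_experiment",
    "binned_incidence",
    "DEMOCRACY_THRESHOLD",
]

#: democracy-coefficient threshold separating the two NSPPM regimes
DEMOCRACY_THRESHOLD = 20 / 2500


@dataclass(frozen=True)
class SISConfig:
    alpha: float
    seed_count: int = 25
    max_steps: int = 1000
    weighted: bool = False

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.seed_count < 1:
            raise ValueError("need at least one initially infected vertex")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass(frozen=True)
class SISResult:
    """Outcome of a single epidemic run."""

    infected_counts: np.ndarray  # currently-infected count per step (incl. t=0)
    incidence_curve: np.ndarray  # |ever infected| / N per step, non-decreasing
    ever_infected: np.ndarray  # boolean mask over vertices
    seeds: np.ndarray  # vertex indices infected at t=0
    termination: str  # "full_incidence" | "extinct" | "timeout"

    @property
    def incidence(self) -> float:
        return float(self.incidence_curve[-1])


def _infection_fractions(
    graph: WeightedDigraph, weighted: bool
) -> tuple[sp.csr_array, np.ndarray]:
    A = graph.adjacency()
    if not weighted:
        A = sp.csr_array(
            (np.ones_like(A.data), A.indices, A.indptr), shape=A.shape
        )
    # column i of A holds the in-edges of i; transpose so a matvec with the
    # infected indicator yields infected in-weight per vertex
    return sp.csr_array(A.T), np.asarray(A.sum(axis=0)).ravel()


def sis_step(
    graph: WeightedDigraph,
    infected: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    weighted: bool = False,
    _cache=None,
) -> np.ndarray:
    """One synchronous SIS update; returns the new infected mask."""
    At, indeg = _cache if _cache is not None else _infection_fractions(graph, weighted)
    frac = np.divide(
        At @ infected.astype(float),
        indeg,
        out=np.zeros(graph.n_vertices),
        where=indeg > 0,
    )
    return rng.random(graph.n_vertices) < frac**alpha


def sis_run(
    graph: WeightedDigraph,
    config: SISConfig,
    levels: HierarchyLevels | None = None,
    rng: np.random.Generator | int | None = None,
) -> SISResult:
    """Run the epidemic from the ``seed_count`` lowest-h vertices.

    Seeds are the vertices with the lowest combined hierarchical level, ties
    broken by vertex order.  The run stops when every vertex has been
    infected at least once (``full_incidence``), no vertex is infected
    (``extinct``), or the horizon is reached (``timeout``).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = graph.n_vertices
    if config.seed_count > n:
        raise ValueError("seed_count exceeds the number of vertices")
    if levels is None:
        levels = hierarchical_levels(graph)
    seeds = np.argsort(levels.h, kind="stable")[: config.seed_count]

    cache = _infection_fractions(graph, config.weighted)
    infected = np.zeros(n, dtype=bool)
    infected[seeds] = True
    ever = infected.copy()
    counts = [int(infected.sum())]
    incidence = [ever.sum() / n]
    termination = "timeout"
    for _ in range(config.max_steps):
        infected = sis_step(
            graph, infected, config.alpha, rng, config.weighted, _cache=cache
        )
        ever |= infected
        counts.append(int(infected.sum()))
        incidence.append(ever.sum() / n)
        if ever.all():
            termination = "full_incidence"
            break
        if not infected.any():
            termination = "extinct"
            break
    return SISResult(
        infected_counts=np.array(counts),
        incidence_curve=np.array(incidence),
        ever_infected=ever,
        seeds=seeds,
        termination=termination,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid for the Monte-Carlo incidence experiment."""

    temperatures: tuple = (0.01, 0.05, 0.2, 0.5, 1.0, 3.0)
    alphas: tuple = (0.5, 1.0, 2.0)
    graphs_per_temperature: int = 20
    runs_per_cell: int = 5
    n: int = 500
    n_edges: int = 2500
    seed_count: int = 25
    max_steps: int = 1000
    democracy_threshold: float = DEMOCRACY_THRESHOLD


def incidence_experiment(
    config: ExperimentConfig = ExperimentConfig(),
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Monte-Carlo incidence over an NSPPM temperature x alpha grid.

    For each temperature, generates ``graphs_per_temperature`` NSPPM graphs,
    computes their hierarchy metrics once, and runs ``runs_per_cell``
    epidemics per alpha.  Returns one row per run with columns
    ``temperature, graph_id, eta_f, rho_f, low_democracy, alpha, run,
    incidence, termination``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    graph_id = 0
    for temperature in config.temperatures:
        for _ in range(config.graphs_per_temperature):
            graph = generate_nsppm(
                n=config.n,
                n_edges=config.n_edges,
                temperature=temperature,
                seed=rng,
            )
            levels = hierarchical_levels(graph)
            metrics = hierarchy_metrics(graph, levels)
            for alpha in config.alphas:
                sis_cfg = SISConfig(
                    alpha=alpha,
                    seed_count=config.seed_count,
                    max_steps=config.max_steps,
                )
                for run in range(config.runs_per_cell):
                    result = sis_run(graph, sis_cfg, levels=levels, rng=rng)
                    rows.append(
                        {
                            "temperature": temperature,
                            "graph_id": graph_id,
                            "eta_f": metrics.eta_f,
                            "rho_f": metrics.rho_f,
                            "low_democracy": metrics.eta_f
                            < config.democracy_threshold,
                            "alpha": alpha,
                            "run": run,
                            "incidence": result.incidence,
                            "termination": result.termination,
                        }
                    )
            graph_id += 1
    return pd.DataFrame(rows)


def binned_incidence(
    table: pd.DataFrame, alpha: float, n_bins: int = 10
) -> pd.DataFrame:
    """Mean incidence in equal-width rho_f bins for one alpha.

    Returns columns ``rho_mid, mean_rho_f, mean_incidence, n_runs`` plus the
    bin edges in ``DataFrame.attrs["bin_edges"]``; empty bins are dropped.
    """
    sub = table[table["alpha"] == alpha]
    if sub.empty:
        raise ValueError(f"no rows with alpha={alpha}")
    edges = np.linspace(sub["rho_f"].min(), sub["rho_f"].max(), n_bins + 1)
    idx = np.clip(np.digitize(sub["rho_f"], edges) - 1, 0, n_bins - 1)
    out = (
        sub.assign(bin=idx)
        .groupby("bin")
        .agg(
            mean_rho_f=("rho_f", "mean"),
            mean_incidence=("incidence", "mean"),
            n_runs=("incidence", "size"),
        )
        .reset_index()
    )
    out["rho_mid"] = (edges[out["bin"]] + edges[out["bin"] + 1]) / 2
    out.attrs["bin_edges"] = edges
    return out
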