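# Methods

## The model

`graphhier` analyses the hierarchical organisation of weighted simple
directed graphs. The starting point is the ecological notion of trophic
levels: in a food web with basal species (zero in-degree vertices), each
consumer sits one level above the weighted mean of its prey. Trophic levels
only exist when every consumer is reachable from a basal vertex; the
framework implemented here removes that restriction.

Write `A` for the weighted adjacency matrix (`A[i, j] > 0` iff there is an
edge i → j), `d` and `δ` for the weighted in- and out-degree vectors,
`L = diag(d) − A` for the in-degree Laplacian, `M = Lᵀ`, and
`Λ = diag(δ) − A` for the out-degree Laplacian. The **forward hierarchical
levels** are

    g = argmin{ ‖x‖₂ : x minimises ‖Mx − d‖₂ }  =  M⁺d,

the minimal-Euclidean-norm least-squares solution, i.e. the pseudoinverse
applied to the in-degree vector. On a graph with basal vertices this
reproduces trophic levels up to an additive shift; on any other simple
graph it is still well defined. The **backward levels** `γ = Λ⁺δ` are the
same construction on the transpose graph, ranking vertices by their
relation to sinks, and the **combined level** is `h = (g − γ)/2`. All
backward quantities in the package are literally the forward quantities of
the transpose graph; this symmetry is exploited throughout and tested.

Per-edge level differences `g_head − g_tail` (forward) and
`γ_tail − γ_head` (backward) summarise to two global metrics, both
weighted by edge weight:

* **democracy coefficient** `η = 1 − mean(differences)` — the amount of
  feedback from influenced vertices onto the vertices that drive the
  dynamics. `η_f = 0` exactly on simply forward influenced graphs (where
  trophic levels exist); balanced graphs (in-degree = out-degree
  everywhere) give `η_f = η_b = 1`.
* **hierarchical incoherence** `ρ = √var(differences)` — the
  generalisation of the trophic incoherence parameter; 0 for perfectly
  layered graphs such as a directed chain.

The per-vertex version of the democracy coefficient is the **influence
centrality**: `e_j` is 1 minus the weighted mean forward difference over
the in-edges of j (empty set → mean 0, so isolated-in vertices get 1), and
`ε_j` the analogue over out-edges of the backward differences. A vertex has
positive forward centrality exactly when it belongs to a minimal source
subgraph, i.e. when its colour can survive the influence dynamics. Two
identities tie everything together and serve as strong self-checks:
`Mg = d ∘ (1 − e)` elementwise, and on strongly connected graphs
`π = diag(δ)²ε / ‖diag(δ)²ε‖₁` is the stationary distribution of the
weight-proportional out-edge random walk.

The **hierarchical decomposition** splits a graph into its minimal source
subgraphs Γᵢ (strongly connected, receiving no external edges), minimal
sink subgraphs Δⱼ, and the core C left after deleting the edges internal
to both families (plus the vertices left isolated). It is computed from
the strongly-connected-component condensation: the minimal source
subgraphs are precisely the condensation's source nodes. This is linear
time and is verified in the tests against brute-force enumeration of the
defining property over all vertex subsets.

## Numerical choices

* Levels are computed with sparse LSMR (tolerances 1e−10, iteration cap
  10·N) followed by one iterative-refinement pass. Started from zero, LSMR
  converges to the minimal-norm solution and the refinement correction
  stays in the row space, so minimality is preserved while the residual
  drops to ~1e−10 — comfortably inside the 1e−8 tolerance at which the
  package's identities are asserted. The pseudoinverse is never formed:
  only its product with a degree vector is needed, which keeps the cost
  near-linear in edges for sparse graphs.
* The test oracle uses `numpy.linalg.lstsq` (SVD-based minimal-norm least
  squares), not an explicit `pinv(M) @ d`: forming the pseudoinverse of
  these frequently ill-conditioned Laplacians and multiplying is
  numerically unstable (observed errors of order 1e13 on ER graphs with
  weak-feedback giant components, with residuals *worse* than the sparse
  solver's), whereas applying it via the SVD is stable.
* Weighted variance is the population variance with weights normalised by
  total edge weight; this reproduces the worked-example values 0.6, 0.433
  and 2.12 exactly.
* The per-vertex backward difference set is grouped by the *tail* vertex
  (out-edges), i.e. backward centrality is defined as forward centrality
  on the transpose graph. Grouping by head — a literal reading of the
  symmetric-looking definition — breaks the equivalence between zero
  centrality and being influenced already on the 3-chain.
* "Centrality is zero" classification uses an absolute tolerance of 1e−8.
* Degenerate inputs: an edgeless graph has well-defined (zero) levels but
  no democracy/incoherence (raises); disconnected graphs are computed
  whole (the least-squares problem block-decomposes) with a warning that
  the sign/zero guarantees hold per weakly connected component; undirected
  inputs are expanded to edge pairs with a warning that h ≡ 0.
* The stationary distribution oracle solves `π(P − I) = 0, Σπ = 1`
  directly rather than by power iteration, so periodic chains (e.g. pure
  cycles) are covered.
* Influence-dynamics absorption is detected by an exact fixed-point test —
  every vertex's closed in-neighbourhood monochromatic, after which no
  future change is possible — rather than by observing an unchanged state
  for one step, which is not a sound certificate for a stochastic map.

## Generators

The **preferential preying model (PPM)** builds unit-weight food-web-like
digraphs: B basal vertices at tentative level 1; each further vertex takes
one uniformly chosen existing vertex as first prey and sits one tentative
level above it; the remaining L − (N − B) edges are drawn without
replacement (Gumbel top-k, exact for weight-proportional sampling) among
absent pairs i → j with non-basal head, with weight
`exp(−(x_j − x_i − 1)² / 2T²)`. The temperature T is the knob: T → 0
yields layered, trophically coherent webs (ρ_f → 0, η_f = 0); large T
approaches uniform wiring. The **NSPPM** variant removes all sources:
the PPM stage runs with budget L − B, then every basal vertex receives one
in-edge drawn with the same kernel (head = basal vertex), which at low T
draws the feedback tail from near level 1 and keeps the forward
influencing subgraphs small — a few 2–6-vertex cycles at the bottom of the
web — while at high T the graphs blur toward ER-like wiring. The basal
count for NSPPM defaults to N/20 (25 at N = 500, the same basal fraction
as the PPM reference configuration). A directed Erdős–Rényi G(n, L)
generator serves as control.

These generators emulate the *structure* the contagion study needs
(temperature-controlled coherence, presence/absence of sources, small
feedback loops at the base) and nothing else: real food webs have body-size
correlations, weighted interactions, and degree heterogeneity that none of
these models reproduce, so passing tests say nothing about fitting real
ecological data.

## The contagion experiment

The SIS rule infects vertex i at t+1 with probability `f_i(t)^α`, where
`f_i` is the fraction of i's in-neighbours currently infected (unweighted
by default, since the generated graphs are unit-weighted; a weighted
option exists) and α > 0 sets the infection difficulty. The current state
of i itself is irrelevant — infected vertices recover unless reinfected —
and zero-in-degree vertices can never be reinfected. Runs start from the
`seed_count` vertices with the lowest combined level h (ties by vertex
order) and stop at full incidence (every vertex infected at least once),
extinction, or a 1000-step horizon.

The experiment grid uses NSPPM graphs with N = 500 vertices and L = 2500
edges, 25 seeds, temperatures (0.01, 0.05, 0.2, 0.5, 1, 3), α ∈ (0.5, 1, 2),
20 graphs per temperature and 5 runs per (T, α) cell — sizes chosen so the
whole surface is recomputed in a few minutes on one CPU while keeping ≥ 20
graphs per cell. Graphs are stratified at democracy coefficient 20/2500:
below it, the graph's few small forward-influencing subgraphs are contained
in the seed set, and once such a subgraph is fully infected every member
has f = 1 forever, so the infection cannot die. Incidence-vs-ρ_f summaries
use 10 equal-width bins over the observed ρ_f range (edges recorded in the
result's metadata).

## Known limitations

* The low-democracy/no-extinction dichotomy is a tendency, not a theorem:
  rare high-temperature graphs consist of one giant weakly-fed-back
  strongly connected component whose η_f falls below 20/2500 while its
  influencing subgraph has hundreds of vertices; a 25-vertex seed set
  cannot cover it and extinction becomes possible. The test suite asserts
  the strict dichotomy and documents this failure mode rather than
  excluding it.
* Exhaustive cross-validation of the decomposition against brute-force
  subset enumeration is run over all labelled digraphs on ≤ 4 vertices
  (4 162 graphs) plus a 500-graph random sample on 5 vertices; the full
  5-vertex family (2²⁰ graphs) is out of proportion to the value of the
  extra coverage.
* Hierarchical levels of weak-feedback graphs are legitimately large (the
  pseudoinverse amplifies long chains against small cycle imbalances), so
  ρ_f outliers of order 10–10³ occur in ER-like ensembles; they are
  genuine, not solver artifacts, and equal-width ρ_f binning can be
  dominated by them.
* Absorption probabilities of the influence dynamics are estimated by
  Monte Carlo only; fundamental-matrix computations are out of scope.
* Conjectured bounds on the democracy coefficient (η ≤ 1) are surveyed
  empirically in the test suite but never asserted.
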