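import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphhier import (
    backward_levels,
    build_graph,
    degree_vectors,
    democracy_coefficients,
    edge_differences,
    forward_levels,
    hierarchical_levels,
    hierarchy_metrics,
    incoherence_parameters,
    influence_centralities,
    influence_centrality_backward,
    influence_centrality_forward,
    laplacians,
    stationary_from_centrality,
    transpose,
)
from graphhier.dynamics import stationary_distribution

from conftest import oracle_backward_levels, oracle_forward_levels, random_digraph


class TestLevels:
    @pytest.mark.parametrize(
        "key, g, gamma",
        [
            ("chain3", (-1, 0, 1), (1, 0, -1)),
            ("weighted_cycle3", (-0.5, 0, 0.5), (0.5, 0, -0.5)),
            ("unit_cycle3", (0, 0, 0), (0, 0, 0)),
            (
                "cycle3_plus_tail",
                (-0.25, -0.25, -0.25, 0.75),
                (2.25, 1.25, 0.25, -3.75),
            ),
        ],
    )
    def test_known_level_vectors(self, toy, key, g, gamma):
        lv = hierarchical_levels(toy[key])
        np.testing.assert_allclose(lv.g, g, atol=1e-8)
        np.testing.assert_allclose(lv.gamma, gamma, atol=1e-8)
        np.testing.assert_allclose(lv.h, (np.array(g) - gamma) / 2, atol=1e-8)

    def test_combined_levels_of_tail_graph(self, toy):
        lv = hierarchical_levels(toy["cycle3_plus_tail"])
        np.testing.assert_allclose(lv.h, (-1.25, -0.75, -0.25, 2.25), atol=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_levels_match_dense_pseudoinverse(self, seed):
        """Iterative minimal-norm solve agrees with M^+ d and Lambda^+ delta."""
        g = random_digraph(np.random.default_rng(seed))
        np.testing.assert_allclose(
            forward_levels(g), oracle_forward_levels(g), atol=1e-8
        )
        np.testing.assert_allclose(
            backward_levels(g), oracle_backward_levels(g), atol=1e-8
        )

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_transpose_antisymmetry(self, seed):
        """g(G) = gamma(G^T) and h(G^T) = -h(G)."""
        g = random_digraph(np.random.default_rng(seed))
        lv, lv_t = hierarchical_levels(g), hierarchical_levels(transpose(g))
        np.testing.assert_allclose(lv.g, lv_t.gamma, atol=1e-8)
        np.testing.assert_allclose(lv_t.h, -lv.h, atol=1e-8)

    def test_undirected_graph_warns_and_has_zero_h(self):
        g = build_graph([(1, 2), (2, 3)], undirected=True)
        with pytest.warns(UserWarning, match="undirected"):
            lv = hierarchical_levels(g)
        np.testing.assert_allclose(lv.h, 0, atol=1e-8)

    def test_disconnected_graph_warns(self):
        g = build_graph([(1, 2), (3, 4)])
        with pytest.warns(UserWarning, match="weakly connected"):
            hierarchical_levels(g)


class TestGraphMetrics:
    @pytest.mark.parametrize(
        "key, eta_f, eta_b, rho_f, rho_b",
        [
            ("chain3", 0.0, 0.0, 0.0, 0.0),
            ("weighted_cycle3", 0.8, 0.8, 0.6, 0.6),
            ("cycle3_plus_tail", 0.75, 0.0, 0.4330127, 2.1213203),
            ("unit_cycle3", 1.0, 1.0, 0.0, 0.0),
        ],
    )
    def test_known_metric_values(self, toy, key, eta_f, eta_b, rho_f, rho_b):
        m = hierarchy_metrics(toy[key])
        assert m.eta_f == pytest.approx(eta_f, abs=1e-6)
        assert m.eta_b == pytest.approx(eta_b, abs=1e-6)
        assert m.rho_f == pytest.approx(rho_f, abs=1e-6)
        assert m.rho_b == pytest.approx(rho_b, abs=1e-6)

    def test_forward_differences_of_weighted_cycle(self, toy):
        diffs = edge_differences(toy["weighted_cycle3"])
        np.testing.assert_allclose(
            sorted(diffs.forward_diff), [-1.0, 0.5, 0.5], atol=1e-8
        )

    def test_edgeless_graph_raises(self):
        g = build_graph([], vertices=[1, 2])
        diffs = edge_differences(g)
        with pytest.raises(ValueError, match="edgeless"):
            democracy_coefficients(diffs)
        with pytest.raises(ValueError, match="edgeless"):
            incoherence_parameters(diffs)

    def test_metrics_recoverable_from_edge_records(self, toy):
        """Weighted mean/std over the per-edge records reproduce the metrics."""
        g = toy["cycle3_plus_tail"]
        diffs = edge_differences(g)
        m = hierarchy_metrics(g)
        mean = np.average(diffs.forward_diff, weights=diffs.weights)
        var = np.average(
            (diffs.forward_diff - mean) ** 2, weights=diffs.weights
        )
        assert 1 - mean == pytest.approx(m.eta_f)
        assert np.sqrt(var) == pytest.approx(m.rho_f)


class TestInfluenceCentrality:
    @pytest.mark.parametrize(
        "key, e, epsilon",
        [
            ("chain3", (1, 0, 0), (0, 0, 1)),
            ("weighted_cycle3", (2, 0.5, 0.5), (0.5, 0.5, 2)),
            ("unit_cycle3", (1, 1, 1), (1, 1, 1)),
        ],
    )
    def test_known_centralities(self, toy, key, e, epsilon):
        cent = influence_centralities(toy[key])
        np.testing.assert_allclose(cent.e, e, atol=1e-8)
        np.testing.assert_allclose(cent.epsilon, epsilon, atol=1e-8)

    def test_weighted_two_cycle_backward_centrality(self, toy):
        eps = influence_centrality_backward(toy["two_cycle_weighted"])
        np.testing.assert_allclose(eps, (1.6, 0.4), atol=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_degree_centrality_identity(self, seed):
        """Mg = d * (1 - e) and Lambda gamma = delta * (1 - epsilon)."""
        g = random_digraph(np.random.default_rng(seed))
        lv = hierarchical_levels(g)
        cent = influence_centralities(g, lv)
        lap, deg = laplacians(g), degree_vectors(g)
        np.testing.assert_allclose(
            lap.M @ lv.g, deg.d * (1 - cent.e), atol=1e-8
        )
        np.testing.assert_allclose(
            lap.Lambda @ lv.gamma, deg.delta * (1 - cent.epsilon), atol=1e-8
        )

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_backward_centrality_is_forward_on_transpose(self, seed):
        g = random_digraph(np.random.default_rng(seed))
        np.testing.assert_allclose(
            influence_centrality_backward(g),
            influence_centrality_forward(transpose(g)),
            atol=1e-8,
        )


class TestStationaryFromCentrality:
    def test_weighted_two_cycle_is_uniform(self, toy):
        pi = stationary_from_centrality(toy["two_cycle_weighted"])
        np.testing.assert_allclose(pi, (0.5, 0.5), atol=1e-8)

    def test_unit_cycle_is_uniform(self, toy):
        pi = stationary_from_centrality(toy["unit_cycle3"])
        np.testing.assert_allclose(pi, np.ones(3) / 3, atol=1e-8)

    def test_matches_random_walk_stationary_distribution(self):
        rng = np.random.default_rng(7)
        found = 0
        while found < 5:
            g = random_digraph(rng, n_max=8)
            if not g.is_strongly_connected():
                continue
            found += 1
            np.testing.assert_allclose(
                stationary_from_centrality(g),
                stationary_distribution(g),
                atol=1e-8,
            )

    def test_requires_strong_connectivity(self, toy):
        with pytest.raises(ValueError, match="strongly connected"):
            stationary_from_centrality(toy["chain3"])
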