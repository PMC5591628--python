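"""Unit tests for the stochastic oracle (graph builder and simulators)."""

import numpy as np
import pytest

from bindingsir.dynamic_net import DynamicParams, free_fraction_dynamic
from bindingsir.kernels import DegreeDistribution
from bindingsir.stochastic import (
    build_configuration_graph,
    estimate_growth_rate,
    simulate_dynamic_sir,
    simulate_static_sir,
)


class TestConfigurationGraph:
    def test_simple_graph_properties(self):
        deg = DegreeDistribution.uniform(3)
        g = build_configuration_graph(2000, deg, seed=17)
        assert g.indices.size == g.indptr[-1]
        for u in range(g.N):
            nbrs = g.indices[g.indptr[u] : g.indptr[u + 1]]
            assert u not in nbrs  # no self-loops
            assert len(set(nbrs.tolist())) == nbrs.size  # no duplicate edges

    def test_adjacency_symmetric(self):
        deg = DegreeDistribution({2: 0.5, 3: 0.5})
        g = build_configuration_graph(1001, deg, seed=3)
        pairs = set()
        for u in range(g.N):
            for v in g.indices[g.indptr[u] : g.indptr[u + 1]]:
                pairs.add((u, int(v)))
        assert all((v, u) in pairs for (u, v) in pairs)

    def test_degrees_from_target_distribution(self):
        deg = DegreeDistribution({2: 0.5, 4: 0.5})
        g = build_configuration_graph(20000, deg, seed=5)
        frac4 = float(np.mean(g.degrees == 4))
        assert abs(frac4 - 0.5) < 0.02

    def test_odd_stub_count_handled(self):
        # uniform degree 3 with odd N: parity cannot be fixed by resampling,
        # so exactly one stub is dropped
        deg = DegreeDistribution.uniform(3)
        g = build_configuration_graph(501, deg, seed=11)
        realized = np.diff(g.indptr)
        assert realized.sum() % 2 == 0
        assert realized.sum() >= 3 * 501 - 1 - 2 * g.n_erased - 1

    def test_determinism(self):
        deg = DegreeDistribution.uniform(3)
        g1 = build_configuration_graph(1000, deg, seed=23)
        g2 = build_configuration_graph(1000, deg, seed=23)
        np.testing.assert_array_equal(g1.indptr, g2.indptr)
        np.testing.assert_array_equal(g1.indices, g2.indices)

    def test_degree_too_large_rejected(self):
        deg = DegreeDistribution.uniform(10)
        with pytest.raises(ValueError, match="population"):
            build_configuration_graph(8, deg, seed=1)


@pytest.fixture(scope="module")
def graph():
    return build_configuration_graph(5000, DegreeDistribution.uniform(3), seed=2)


class TestStaticSimulator:

    def test_no_transmission_without_contact_rate(self, graph):
        res = simulate_static_sir(graph, beta=1e-12, gamma=1.0, initial_infected=5,
                                  seed=4, replicates=3)
        np.testing.assert_allclose(res.final_sizes, 5 / graph.N, atol=1e-12)

    def test_counts_monotone_and_ordered(self, graph):
        res = simulate_static_sir(graph, 2.0, 1.0, 5, seed=8, replicates=5)
        assert np.all(np.diff(res.cum_infections, axis=1) >= 0.0)
        assert np.all(np.diff(res.cum_recoveries, axis=1) >= 0.0)
        # a recovery never precedes its infection
        assert np.all(res.cum_recoveries <= res.cum_infections)

    def test_final_size_equals_cumulative_infections(self, graph):
        res = simulate_static_sir(graph, 2.0, 1.0, 5, seed=8, replicates=5,
                                  t_grid=np.linspace(0.0, 200.0, 51))
        np.testing.assert_allclose(
            res.final_sizes, res.cum_infections[:, -1] / graph.N, atol=1e-12
        )

    def test_byte_for_byte_determinism(self, graph):
        a = simulate_static_sir(graph, 2.0, 1.0, 5, seed=99, replicates=4)
        b = simulate_static_sir(graph, 2.0, 1.0, 5, seed=99, replicates=4)
        assert a.final_sizes.tobytes() == b.final_sizes.tobytes()
        assert a.cum_infections.tobytes() == b.cum_infections.tobytes()
        assert a.cum_recoveries.tobytes() == b.cum_recoveries.tobytes()

    def test_replicates_extend_by_fixed_stride(self, graph):
        # the first replicates of a longer run coincide with a shorter run
        short = simulate_static_sir(graph, 2.0, 1.0, 5, seed=99, replicates=2)
        long = simulate_static_sir(graph, 2.0, 1.0, 5, seed=99, replicates=4)
        np.testing.assert_array_equal(short.final_sizes, long.final_sizes[:2])

    def test_initial_infected_validated(self, graph):
        with pytest.raises(ValueError):
            simulate_static_sir(graph, 2.0, 1.0, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_static_sir(graph, 2.0, 1.0, graph.N, seed=1)


class TestDynamicSimulator:
    def test_partnership_burn_in_reaches_stationary_free_fraction(self):
        params = DynamicParams(beta=2.0, gamma=1.0, rho=2.0, sigma=1.0, n=3)
        res = simulate_dynamic_sir(5000, params, 5, seed=31, replicates=4)
        F = free_fraction_dynamic(2.0, 1.0)
        assert abs(res.free_fraction[:, 0].mean() - F) < 0.02

    def test_byte_for_byte_determinism(self):
        params = DynamicParams(beta=2.0, gamma=1.0, rho=2.0, sigma=1.0, n=3)
        a = simulate_dynamic_sir(2000, params, 5, seed=77, replicates=3)
        b = simulate_dynamic_sir(2000, params, 5, seed=77, replicates=3)
        assert a.final_sizes.tobytes() == b.final_sizes.tobytes()
        assert a.cum_infections.tobytes() == b.cum_infections.tobytes()
        assert a.free_fraction.tobytes() == b.free_fraction.tobytes()

    def test_counts_consistent(self):
        params = DynamicParams(beta=2.0, gamma=1.0, rho=2.0, sigma=1.0, n=3)
        res = simulate_dynamic_sir(3000, params, 5, seed=13, replicates=3,
                                   t_grid=np.linspace(0.0, 100.0, 101))
        assert np.all(np.diff(res.cum_infections, axis=1) >= 0.0)
        assert np.all(res.cum_recoveries <= res.cum_infections)
        np.testing.assert_allclose(
            res.final_sizes, res.cum_infections[:, -1] / res.N, atol=1e-12
        )

    def test_turnover_keeps_population_susceptible_supply(self):
        # with births/deaths the epidemic need not exhaust the susceptibles
        params = DynamicParams(beta=3.0, gamma=1.0, rho=2.0, sigma=1.0, n=3)
        res = simulate_dynamic_sir(2000, params, 10, seed=21, replicates=2,
                                   t_grid=np.linspace(0.0, 30.0, 31), mu=0.2)
        assert np.all(res.final_sizes <= 5.0)  # reinfection-free counter still bounded
        assert np.all(np.diff(res.cum_infections, axis=1) >= 0.0)


class TestGrowthRateEstimator:
    def test_recovers_exact_exponential(self):
        t = np.linspace(0.0, 10.0, 200)
        series = 3.0 * np.exp(0.7 * t)
        assert estimate_growth_rate(t, series, (1.0, 9.0)) == pytest.approx(
            0.7, rel=1e-12
        )

    def test_rejects_nonpositive_values(self):
        t = np.linspace(0.0, 5.0, 50)
        series = np.ones_like(t)
        series[10] = 0.0
        with pytest.raises(ValueError, match="positive"):
            estimate_growth_rate(t, series, (0.0, 5.0))

    def test_rejects_empty_window(self):
        t = np.linspace(0.0, 5.0, 50)
        with pytest.raises(ValueError, match="window"):
            estimate_growth_rate(t, np.ones_like(t), (10.0, 20.0))
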