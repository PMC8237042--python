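import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

import netdistancing as nd
from netdistancing import Graph
from netdistancing.mcmc import _initial_state

from conftest import random_graph


class TestAcceptanceProbability:
    def test_nu_zero_accepts_everything(self):
        assert nd.acceptance_probability(5.0, 9.0, 0.0) == 1.0

    def test_downhill_always_accepted(self):
        assert nd.acceptance_probability(3.0, 2.9, 1000.0) == 1.0
        assert nd.acceptance_probability(3.0, 3.0, 1000.0) == 1.0

    def test_uphill_closed_form(self):
        assert nd.acceptance_probability(3.0, 3.5, 2.0) == pytest.approx(math.exp(-1.0))

    def test_huge_uphill_underflows_to_zero(self):
        assert nd.acceptance_probability(1.0, 5.0, 1000.0) == 0.0

    def test_negative_nu_rejected(self):
        with pytest.raises(ValueError):
            nd.acceptance_probability(1.0, 2.0, -1.0)


class TestProposeSwap:
    def test_single_pair_swap_is_deterministic(self, path4):
        state = _initial_state(path4, 1 / 3, np.random.default_rng(0))
        # reduce to |kept|=1, |removed|=1 by hand
        state.kept_idx, state.removed_idx = state.kept_idx[:1], state.removed_idx[:1]
        new = nd.propose_swap(state, np.random.default_rng(1))
        assert new.kept_edges == state.removed_edges
        assert new.removed_edges == state.kept_edges

    def test_proposal_differs_in_exactly_two_memberships(self):
        g = random_graph(20, 0.3, 1)
        state = _initial_state(g, 0.4, np.random.default_rng(2))
        new = nd.propose_swap(state, np.random.default_rng(3))
        assert len(state.kept_edges ^ new.kept_edges) == 2
        assert state.kept_edges | state.removed_edges == new.kept_edges | new.removed_edges

    def test_swap_pairs_uniform(self):
        """With |kept|=3, |removed|=2 each of the 6 (kept, removed) swap
        pairs is proposed equally often."""
        g = Graph.from_edges(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)])
        state = _initial_state(g, 0.4, np.random.default_rng(0))
        assert (len(state.kept_idx), len(state.removed_idx)) == (3, 2)
        rng = np.random.default_rng(42)
        counts = Counter(frozenset(nd.propose_swap(state, rng).kept_edges) for _ in range(12000))
        assert len(counts) == 6
        _, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_empty_side_refused(self, path4):
        state = _initial_state(path4, 1 / 3, np.random.default_rng(0))
        state.removed_idx = state.removed_idx[:0]
        with pytest.raises(ValueError):
            nd.propose_swap(state, np.random.default_rng(0))


class TestExactStationaryDistribution:
    def test_nu_zero_is_uniform(self, path4):
        dist = nd.exact_stationary_distribution(path4, 1 / 3, 0.0)
        assert len(dist) == 3
        for p in dist.values():
            assert p == pytest.approx(1 / 3)

    def test_path4_boltzmann_weights(self, path4):
        """Removing the middle edge leaves K2+K2 (lambda=1); an end edge
        leaves P3+isolated (lambda=sqrt 2).  At nu=1 the middle-removal
        probability is exp(-1)/(exp(-1) + 2 exp(-sqrt 2))."""
        dist = nd.exact_stationary_distribution(path4, 1 / 3, 1.0)
        p_middle = dist[frozenset({(0, 1), (2, 3)})]
        expected = math.exp(-1) / (math.exp(-1) + 2 * math.exp(-math.sqrt(2)))
        assert p_middle == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4307, abs=5e-5)
        for kept, p in dist.items():
            if kept != frozenset({(0, 1), (2, 3)}):
                assert p == pytest.approx((1 - expected) / 2, abs=1e-12)

    def test_probabilities_sum_to_one(self):
        g = random_graph(8, 0.4, 3)
        dist = nd.exact_stationary_distribution(g, 0.5, 2.0)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_refuses_large_state_space(self):
        g = nd.generate_ba(50, 5, seed=0)
        with pytest.raises(ValueError):
            nd.exact_stationary_distribution(g, 0.5, 1.0)


class TestMcmcRun:
    def test_zero_steps_equals_random_removal(self, path4):
        g = nd.generate_ba(30, 3, seed=5)
        trace = nd.mcmc_run(g, 0.4, 1000.0, steps=0, seed=17)
        assert trace.final_graph == nd.random_removal(g, 0.4, seed=17)

    def test_edge_count_conserved_and_subgraph(self):
        g = random_graph(25, 0.4, 2)
        trace = nd.mcmc_run(g, 0.5, 5.0, steps=300, seed=3)
        kept_target = g.n_edges - nd.n_edges_to_remove(g.n_edges, 0.5)
        assert trace.final_graph.n_edges == kept_target
        assert trace.final_graph.edges <= g.edges
        assert len(trace.energies) == 300 and (trace.energies >= 0).all()

    def test_identical_seeds_identical_traces(self):
        g = random_graph(20, 0.4, 9)
        a = nd.mcmc_run(g, 0.4, 10.0, steps=200, seed=4)
        b = nd.mcmc_run(g, 0.4, 10.0, steps=200, seed=4)
        assert np.array_equal(a.energies, b.energies)
        assert np.array_equal(a.accepted, b.accepted)
        assert a.final_graph == b.final_graph

    def test_nu_zero_has_no_drift(self):
        """At nu=0 every proposal is accepted and the energy fluctuates
        around the generic-removal mean with no systematic trend."""
        g = nd.generate_ba(80, 8, seed=1)
        trace = nd.mcmc_run(g, 0.4, 0.0, steps=2000, seed=2)
        assert trace.accepted.all()
        half = trace.energies[1000:]
        slope = np.polyfit(np.arange(len(half)), half, 1)[0]
        assert abs(slope) < 5e-4
        rand_mean = np.mean(
            [nd.largest_eigenvalue(nd.random_removal(g, 0.4, s)) for s in range(40)]
        )
        assert np.mean(half) == pytest.approx(rand_mean, abs=0.3)

    def test_degenerate_rho_rejected(self, path4):
        with pytest.raises(ValueError):
            nd.mcmc_run(path4, 0.05, 1.0, steps=10, seed=0)  # rounds to 0 removed


class TestSampleEnsemble:
    def test_single_config_mean_is_final_energy(self):
        factory = lambda s: nd.generate_ba(40, 4, seed=s)
        summary = nd.sample_ensemble(factory, 0.4, 10.0, steps=50, n_configs=1, seed=3)
        assert summary.mean == summary.final_energies[0]
        assert summary.n_configs == 1
        assert summary.final_graphs[0].n_edges == 144 - nd.n_edges_to_remove(144, 0.4)

    def test_mean_energy_non_increasing_in_nu(self):
        """Stronger genericity bias (larger nu) lowers the steady-state
        spectral radius: the ensemble mean is monotone down the nu grid."""
        factory = lambda s: nd.generate_ba(50, 5, seed=s)
        means = [
            nd.sample_ensemble(
                factory, 0.4, nu, steps=1500, n_configs=6, seed=11, keep_graphs=False
            ).mean
            for nu in (0.0, 10.0, 100.0, 1000.0)
        ]
        assert all(a >= b - 0.05 for a, b in zip(means, means[1:]))

    def test_nu_zero_matches_generic_ensemble(self):
        factory = lambda s: nd.generate_ba(50, 5, seed=s)
        summary = nd.sample_ensemble(factory, 0.4, 0.0, steps=400, n_configs=8, seed=5, keep_graphs=False)
        rand = [
            nd.largest_eigenvalue(nd.random_removal(nd.generate_ba(50, 5, seed=s), 0.4, s))
            for s in range(40)
        ]
        assert summary.mean == pytest.approx(np.mean(rand), abs=0.4)


class TestDetailedBalance:
    @pytest.mark.parametrize("nu", [0.0, 1.0, 5.0])
    def test_occupancy_matches_boltzmann_on_path4(self, path4, nu):
        """Long-run state occupancy on the enumerable P4 instance matches
        exp(-nu lambda_max)/Z from exact enumeration (chi-square)."""
        exact = nd.exact_stationary_distribution(path4, 1 / 3, nu)
        steps, burn, thin = 30_000, 2_000, 10
        trace_states = []
        g = path4
        rng = np.random.default_rng(123)
        state = _initial_state(g, 1 / 3, rng)
        for t in range(steps):
            prop = nd.propose_swap(state, rng)
            if rng.random() < nd.acceptance_probability(state.energy, prop.energy, nu):
                state = prop
            if t >= burn and t % thin == 0:
                trace_states.append(state.kept_edges)
        counts = Counter(trace_states)
        observed = [counts.get(s, 0) for s in exact]
        expected = np.array([exact[s] for s in exact]) * len(trace_states)
        _, p = chisquare(observed, expected)
        assert p > 0.01
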