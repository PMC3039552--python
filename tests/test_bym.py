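import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, poisson

from arealrisk import (
    AreaGraph,
    BYMState,
    IncidenceDataset,
    MCMCConfig,
    fit_bym,
    log_posterior_bym,
    model_fit_stats,
    summarize_sir,
)
from arealrisk.config import INCIDENCE_PRIORS
from arealrisk.containers import PosteriorDraws
from arealrisk.diagnostics import mcse
from arealrisk.quadrature import bym_posterior_means
from arealrisk.simulate import make_geography, simulate_incidence


def reference_log_posterior(state, data, graph, priors):
    """Independent re-implementation: explicit scipy densities and an
    explicit loop over neighbour pairs."""
    total = 0.0
    for i in range(data.n_areas):
        lam = data.e[i] * math.exp(state.alpha + state.u[i] + state.v[i])
        total += poisson.logpmf(int(data.y[i]), lam)
    rank = graph.n_areas - graph.n_components()
    q = 0.0
    for i in range(graph.n_areas):
        for j in graph.neighbours[i]:
            if j > i:
                q += (state.u[i] - state.u[j]) ** 2
    total += (rank / 2) * math.log(state.tau_u) - state.tau_u * q / 2
    for i in range(graph.n_areas):
        total += norm.logpdf(state.v[i], 0, 1 / math.sqrt(state.tau_v))
    total += norm.logpdf(state.alpha, 0, math.sqrt(priors.alpha_variance))
    for tau, prior in ((state.tau_u, priors.tau_u), (state.tau_v, priors.tau_v)):
        total += gamma_dist.logpdf(tau, prior.shape, scale=1 / prior.rate)
    return total


class TestLogPosterior:
    def test_matches_independent_oracle_on_random_states(self, path3_graph, path3_data):
        rng = np.random.default_rng(4)
        priors = INCIDENCE_PRIORS[3]
        for _ in range(10):
            u = rng.normal(size=3)
            u -= u.mean()
            state = BYMState(
                alpha=float(rng.normal()), u=u, v=rng.normal(size=3),
                tau_u=float(rng.gamma(2, 1)), tau_v=float(rng.gamma(2, 1)),
            )
            ours = log_posterior_bym(state, path3_data, path3_graph, priors)
            ref = reference_log_posterior(state, path3_data, path3_graph, priors)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_disconnected_pairs_use_component_rank(self):
        graph = AreaGraph(
            ("a", "b", "c", "d"),
            (frozenset({1}), frozenset({0}), frozenset({3}), frozenset({2})),
        )
        data = IncidenceDataset(("a", "b", "c", "d"),
                                np.array([3, 4, 5, 6]), np.full(4, 4.0))
        u = np.array([0.3, -0.3, 0.2, -0.2])
        state = BYMState(alpha=0.1, u=u, v=np.zeros(4), tau_u=2.0, tau_v=1.0)
        ours = log_posterior_bym(state, data, graph)
        ref = reference_log_posterior(state, data, graph, INCIDENCE_PRIORS[3])
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_sum_to_zero_violation_rejected(self, path3_graph, path3_data):
        state = BYMState(alpha=0.0, u=np.array([0.5, 0.5, 0.5]),
                         v=np.zeros(3), tau_u=1.0, tau_v=1.0)
        with pytest.raises(ValueError, match="sum-to-zero"):
            log_posterior_bym(state, path3_data, path3_graph)

    def test_invariant_under_area_relabelling(self, path3_graph, path3_data):
        perm = [2, 0, 1]
        graph_p = AreaGraph(
            tuple(path3_graph.area_ids[i] for i in perm),
            tuple(
                frozenset(perm.index(j) for j in path3_graph.neighbours[i])
                for i in perm
            ),
        )
        data_p = IncidenceDataset(
            graph_p.area_ids, path3_data.y[perm], path3_data.e[perm]
        )
        u = np.array([0.2, -0.5, 0.3])
        v = np.array([0.1, 0.0, -0.4])
        s = BYMState(0.3, u, v, 1.5, 2.5)
        s_p = BYMState(0.3, u[perm], v[perm], 1.5, 2.5)
        assert log_posterior_bym(s, path3_data, path3_graph) == pytest.approx(
            log_posterior_bym(s_p, data_p, graph_p), abs=1e-12
        )


class TestFitBym:
    def test_same_seed_is_bit_identical(self, path3_graph, path3_data):
        cfg = MCMCConfig(200, 200, 2)
        a = fit_bym(path3_data, path3_graph, mcmc=cfg, seed=42)
        b = fit_bym(path3_data, path3_graph, mcmc=cfg, seed=42)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])

    def test_isolate_graph_rejected(self, path3_data):
        graph = AreaGraph(("a", "b", "c"),
                          (frozenset({1}), frozenset({0}), frozenset()))
        with pytest.raises(ValueError, match="isolate"):
            fit_bym(path3_data, graph)

    def test_zero_expected_rejected(self, path3_graph):
        data = IncidenceDataset(("a", "b", "c"), np.array([1, 2, 3]),
                                np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="expected"):
            fit_bym(data, path3_graph)

    def test_null_simulation_stays_near_one(self):
        _, graph = make_geography(5, 10, 0, seed=1)
        sim = simulate_incidence(graph, alpha=0.0, sigma_u=0.0, sigma_v=0.0,
                                 expected=np.full(50, 100.0), seed=8)
        draws = fit_bym(sim.data, graph, mcmc=MCMCConfig(1500, 1500, 3), seed=5)
        med = np.median(draws.theta(), axis=0)
        assert np.all(med > 0.9) and np.all(med < 1.1)

    def test_two_area_fit_matches_quadrature(self):
        graph = AreaGraph(("a", "b"), (frozenset({1}), frozenset({0})),
                          np.array([[0.0, 0.0], [1.0, 0.0]]))
        data = IncidenceDataset(("a", "b"), np.array([3, 7]), np.array([5.0, 5.0]))
        oracle = bym_posterior_means(data, graph)
        draws = fit_bym(data, graph, mcmc=MCMCConfig(20_000, 20_000, 10), seed=3)
        theta = draws.theta()
        for i in range(2):
            err = mcse(theta[:, i])
            assert abs(theta[:, i].mean() - oracle[i]) < 3 * err

    def test_low_count_area_shrinks_toward_neighbours(self):
        _, graph = make_geography(3, 3, 0, seed=0)
        e = np.full(9, 50.0)
        e[4] = 1.0
        y = np.round(e).astype(int)
        y[4] = 4  # raw ratio 4 on a tiny expected count
        data = IncidenceDataset(graph.area_ids, y, e)
        draws = fit_bym(data, graph, mcmc=MCMCConfig(1500, 1500, 3), seed=2)
        med = np.median(draws.theta(), axis=0)
        assert 1.0 < med[4] < 4.0
        assert abs(med[4] - 1.0) < abs(4.0 - 1.0) / 2


class TestSummaries:
    def make_draws(self, theta_chain):
        t = len(theta_chain)
        params = {
            "alpha": np.log(np.asarray(theta_chain, dtype=float)),
            "u": np.zeros((t, 1)),
            "v": np.zeros((t, 1)),
            "tau_u": np.ones(t),
            "tau_v": np.ones(t),
        }
        return PosteriorDraws("incidence", ("a",), params,
                              MCMCConfig(1, t, 1), seed=0)

    def test_constant_chain_degenerates(self):
        est = summarize_sir(self.make_draws([1.3] * 100))
        assert est.median[0] == pytest.approx(1.3)
        assert est.lo95[0] == pytest.approx(1.3)
        assert est.hi95[0] == pytest.approx(1.3)

    def test_percentiles_match_order_statistics(self):
        vals = np.arange(1, 10001) / 5000.0
        est = summarize_sir(self.make_draws(vals))
        assert est.median[0] == pytest.approx((vals[4999] + vals[5000]) / 2)
        # linear interpolation between order statistics (type 7)
        h = 0.025 * 9999
        k = int(h)
        expect_lo = vals[k] + (h - k) * (vals[k + 1] - vals[k])
        assert est.lo95[0] == pytest.approx(expect_lo)

    def test_point_mass_draws_give_zero_pd(self, path3_graph, path3_data):
        t = 4
        params = {
            "alpha": np.full(t, 0.2),
            "u": np.tile(np.array([0.1, 0.0, -0.1]), (t, 1)),
            "v": np.tile(np.array([0.05, -0.05, 0.0]), (t, 1)),
            "tau_u": np.ones(t),
            "tau_v": np.ones(t),
        }
        draws = PosteriorDraws("incidence", path3_graph.area_ids, params,
                               MCMCConfig(1, t, 1), seed=0)
        stats = model_fit_stats(draws, path3_data, path3_graph)
        assert stats["pD"] == pytest.approx(0.0, abs=1e-9)
        lam = path3_data.e * np.exp(0.2 + params["u"][0] + params["v"][0])
        dev = -2 * poisson.logpmf(path3_data.y.astype(int), lam).sum()
        assert stats["DIC"] == pytest.approx(dev, abs=1e-9)
        # u has spread here, so the spatial fraction is positive; a flat
        # field gives zero
        params["u"] = np.zeros((t, 3))
        draws0 = PosteriorDraws("incidence", path3_graph.area_ids, params,
                                MCMCConfig(1, t, 1), seed=0)
        assert model_fit_stats(draws0, path3_data, path3_graph)[
            "spatial_fraction"] == 0.0

    def test_flat_map_gives_unit_ratio90(self, path3_graph, path3_data):
        t = 4
        params = {
            "alpha": np.zeros(t),
            "u": np.zeros((t, 3)),
            "v": np.zeros((t, 3)),
            "tau_u": np.ones(t),
            "tau_v": np.ones(t),
        }
        draws = PosteriorDraws("incidence", path3_graph.area_ids, params,
                               MCMCConfig(1, t, 1), seed=0)
        assert model_fit_stats(draws, path3_data, path3_graph)["ratio90"] == 1.0
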