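import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, poisson

from arealrisk import (
    AreaGraph,
    MCMCConfig,
    SurvivalState,
    adjusted_deaths,
    fit_excess_mortality,
    log_posterior_excess,
    point_estimates,
    summarize_rer,
)
from arealrisk.config import SURVIVAL_PRIORS
from arealrisk.diagnostics import mcse
from arealrisk.prep import SurvivalCellTable
from arealrisk.quadrature import excess_posterior_means


def toy_cells(path3=True):
    """Hand-sized cell table: one broad age group, two follow-up years,
    three areas."""
    area_ids = ("a", "b", "c")
    k = np.zeros(6, dtype=int)
    j = np.array([1, 1, 1, 2, 2, 2])
    i = np.array([0, 1, 2, 0, 1, 2])
    y = np.array([40.0, 50.0, 60.0, 30.0, 40.0, 50.0])
    d = np.array([9, 12, 22, 4, 6, 10])
    dstar = np.array([1.0, 1.2, 1.5, 0.8, 1.0, 1.2])
    return SurvivalCellTable(area_ids, ("0-59",), 2, k, j, i, y, d, dstar)


def reference_log_posterior(state, cells, graph, priors):
    total = 0.0
    for c in range(cells.n_cells):
        lp = (state.alpha[cells.interval[c] - 1]
              + state.beta[cells.age_idx[c]]
              + state.u[cells.area_idx[c]]
              + state.v[cells.area_idx[c]])
        mu = cells.dstar[c] + cells.y[c] * math.exp(lp)
        total += poisson.logpmf(int(cells.d[c]), mu)
    rank = graph.n_areas - graph.n_components()
    q = 0.0
    for a in range(graph.n_areas):
        for b in graph.neighbours[a]:
            if b > a:
                q += (state.u[a] - state.u[b]) ** 2
    total += (rank / 2) * math.log(state.tau_u) - state.tau_u * q / 2
    for a in range(graph.n_areas):
        total += norm.logpdf(state.v[a], 0, 1 / math.sqrt(state.tau_v))
    for coef in list(state.alpha) + list(state.beta[1:]):
        total += norm.logpdf(coef, 0, math.sqrt(priors.alpha_variance))
    for tau, prior in ((state.tau_u, priors.tau_u), (state.tau_v, priors.tau_v)):
        total += gamma_dist.logpdf(tau, prior.shape, scale=1 / prior.rate)
    return total


class TestLogPosteriorExcess:
    def test_matches_independent_cell_sum_oracle(self, path3_graph):
        cells = toy_cells()
        rng = np.random.default_rng(12)
        priors = SURVIVAL_PRIORS[3]
        for _ in range(8):
            u = rng.normal(scale=0.3, size=3)
            u -= u.mean()
            beta = np.array([0.0])
            state = SurvivalState(
                alpha=rng.normal(scale=0.5, size=2), beta=beta, u=u,
                v=rng.normal(scale=0.3, size=3),
                tau_u=float(rng.gamma(2, 1)), tau_v=float(rng.gamma(2, 1)),
            )
            ours = log_posterior_excess(state, cells, path3_graph, priors)
            ref = reference_log_posterior(state, cells, path3_graph, priors)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_null_state_gives_unit_excess_hazard(self, path3_graph):
        # with all effects zero, mu = dstar + y in every cell
        cells = toy_cells()
        state = SurvivalState(np.zeros(2), np.zeros(1), np.zeros(3),
                              np.zeros(3), 1.0, 1.0)
        ours = log_posterior_excess(state, cells, path3_graph)
        lik = poisson.logpmf(cells.d, cells.dstar + cells.y).sum()
        ref = reference_log_posterior(state, cells, path3_graph, SURVIVAL_PRIORS[3])
        assert ours == pytest.approx(ref, abs=1e-10)
        assert ref == pytest.approx(
            lik + (ref - lik), abs=1e-12
        )  # likelihood part is exactly the dstar + y form

    def test_vanishing_excess_hazard_tends_to_background_only(self, path3_graph):
        # as the linear predictor goes to -inf, mu collapses onto d*
        cells = toy_cells()
        state = SurvivalState(np.full(2, -40.0), np.zeros(1), np.zeros(3),
                              np.zeros(3), 1.0, 1.0)
        ours = log_posterior_excess(state, cells, path3_graph)
        assert ours == pytest.approx(reference_log_posterior(
            state, cells, path3_graph, SURVIVAL_PRIORS[3]), abs=1e-10)
        mu_limit = cells.dstar + cells.y * math.exp(-40.0)
        assert np.allclose(mu_limit, cells.dstar, rtol=1e-15, atol=1e-12)

    def test_negative_expected_deaths_rejected(self, path3_graph):
        cells = toy_cells()
        bad = SurvivalCellTable(cells.area_ids, cells.age_groups, 2,
                                cells.age_idx, cells.interval, cells.area_idx,
                                cells.y, cells.d, cells.dstar)
        object.__setattr__(bad, "dstar", cells.dstar - 2.0)
        state = SurvivalState(np.zeros(2), np.zeros(1), np.zeros(3),
                              np.zeros(3), 1.0, 1.0)
        with pytest.raises(ValueError, match="negative expected"):
            log_posterior_excess(state, bad, path3_graph)

    def test_nonzero_reference_beta_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            SurvivalState(np.zeros(2), np.array([0.5]), np.zeros(3),
                          np.zeros(3), 1.0, 1.0)


class TestFitExcess:
    def test_same_seed_is_bit_identical(self, path3_graph):
        cells = toy_cells()
        cfg = MCMCConfig(200, 200, 2)
        a = fit_excess_mortality(cells, path3_graph, mcmc=cfg, seed=9)
        b = fit_excess_mortality(cells, path3_graph, mcmc=cfg, seed=9)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])

    def test_toy_fit_matches_quadrature(self, path3_graph):
        # oracle comparison on the centred log relative excess risk: the
        # shift-invariant contrasts the map is actually about (see the
        # quadrature module on why the un-centred mean is ill posed)
        cells = toy_cells()
        oracle = excess_posterior_means(cells, path3_graph, n_nodes=4,
                                        phi_step=0.6)
        draws = fit_excess_mortality(cells, path3_graph,
                                     mcmc=MCMCConfig(20_000, 20_000, 10), seed=2)
        s = draws.params["u"] + draws.params["v"]
        s = s - s.mean(axis=1, keepdims=True)
        for i in range(3):
            err = mcse(s[:, i])
            assert abs(s[:, i].mean() - oracle[i]) < 3 * err


class TestRerAndAdjustedDeaths:
    def test_null_effects_give_unit_rer(self, path3_graph):
        t = 5
        params = {
            "alpha": np.zeros((t, 2)),
            "beta": np.zeros((t, 1)),
            "u": np.zeros((t, 3)),
            "v": np.zeros((t, 3)),
            "tau_u": np.ones(t),
            "tau_v": np.ones(t),
        }
        from arealrisk.containers import PosteriorDraws

        draws = PosteriorDraws("survival", path3_graph.area_ids, params,
                               MCMCConfig(1, t, 1), seed=0)
        est = summarize_rer(draws)
        assert np.all(est.median == 1.0)
        assert np.all(est.lo95 == 1.0) and np.all(est.hi95 == 1.0)

    def test_adjusted_equals_expected_at_null_rer(self):
        cells = toy_cells()
        state = SurvivalState(np.array([-1.0, -1.5]), np.zeros(1),
                              np.zeros(3), np.zeros(3), 1.0, 1.0)
        adj, exp_ = adjusted_deaths(state, cells)
        assert np.array_equal(adj, exp_)

    def test_no_person_time_leaves_background_deaths(self):
        cells = toy_cells()
        zeroed = SurvivalCellTable(cells.area_ids, cells.age_groups, 2,
                                   cells.age_idx, cells.interval,
                                   cells.area_idx, np.zeros(6), cells.d,
                                   cells.dstar)
        state = SurvivalState(np.zeros(2), np.zeros(1), np.zeros(3),
                              np.zeros(3), 1.0, 1.0)
        adj, exp_ = adjusted_deaths(state, zeroed)
        per_area_dstar = np.array([1.8, 2.2, 2.7])
        assert np.allclose(adj, per_area_dstar)
        assert np.allclose(exp_, per_area_dstar)

    def test_two_cell_hand_example(self):
        # two areas, one cell each: A_i = y e^alpha e^beta RER_i + dstar
        cells = SurvivalCellTable(("a", "b"), ("0-59",), 1,
                                  np.zeros(2, dtype=int), np.ones(2, dtype=int),
                                  np.array([0, 1]), np.array([10.0, 20.0]),
                                  np.array([3, 5]), np.array([0.5, 0.7]))
        u = np.array([0.2, -0.2])
        v = np.array([0.1, -0.1])
        state = SurvivalState(np.array([-1.0]), np.zeros(1), u, v, 1.0, 1.0)
        adj, exp_ = adjusted_deaths(state, cells)
        assert adj[0] == pytest.approx(10 * math.exp(-1.0) * math.exp(0.3) + 0.5)
        assert adj[1] == pytest.approx(20 * math.exp(-1.0) * math.exp(-0.3) + 0.7)
        assert exp_[0] == pytest.approx(10 * math.exp(-1.0) + 0.5)
        assert exp_[1] == pytest.approx(20 * math.exp(-1.0) + 0.7)

    def test_raising_u_raises_adjusted_not_expected(self):
        cells = toy_cells()
        base = SurvivalState(np.array([-1.0, -1.5]), np.zeros(1),
                             np.array([0.1, 0.0, -0.1]), np.zeros(3), 1.0, 1.0)
        up = SurvivalState(np.array([-1.0, -1.5]), np.zeros(1),
                           np.array([0.4, 0.0, -0.1]), np.zeros(3), 1.0, 1.0)
        a0, e0 = adjusted_deaths(base, cells)
        a1, e1 = adjusted_deaths(up, cells)
        assert a1[0] > a0[0]
        assert np.array_equal(e0, e1)

    def test_point_estimates_reference_category_preserved(self, path3_graph):
        cells = toy_cells()
        draws = fit_excess_mortality(cells, path3_graph,
                                     mcmc=MCMCConfig(300, 300, 3), seed=4)
        state = point_estimates(draws)
        assert state.beta[0] == 0.0
        assert len(state.alpha) == 2
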