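"""Self-contained validation studies.

Each function runs one simulation study end to end — generate synthetic
inputs, run the relevant estimator, measure the outcome — and returns its
metrics as plain floats.  The studies double as the package's regression
harness: sampler-versus-quadrature agreement on a tiny model, parameter
recovery and null calibration on lattices, clustering-test type-I error,
and convergence-diagnostic calibration.  All randomness is derived from the
single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .bym import fit_bym, summarize_sir
from .cluster import modelled_observed_incidence, tango_meet
from .config import (
    DEFAULT_BROAD_AGE_GROUPS,
    DESK_SCALE,
    MCMCConfig,
    PRODUCTION_SCALE_INCIDENCE,
)
from .containers import IncidenceDataset
from .diagnostics import geweke_z, mcse
from .geography import AreaGraph, repair_isolates
from .prep import apply_survival_exclusions, collapse_person_time
from .quadrature import bym_posterior_means
from .simulate import (
    make_geography,
    simulate_incidence,
    simulate_populations_and_lifetable,
    simulate_survival_records,
)
from .survival import (
    SurvivalState,
    adjusted_deaths,
    fit_excess_mortality,
    summarize_rer,
)

__all__ = [
    "bym_quadrature_agreement",
    "bym_lattice_recovery",
    "null_false_positive_study",
    "meet_type_one_error",
    "survival_recovery_study",
    "adjusted_deaths_identity",
    "geweke_calibration",
]

_WINDOW = ("1998-01-01", "2007-12-31")


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def toy_path3() -> tuple[AreaGraph, IncidenceDataset]:
    """The three-area path toy used for oracle comparisons."""
    graph = AreaGraph(
        ("a", "b", "c"),
        (frozenset({1}), frozenset({0, 2}), frozenset({1})),
        np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
    )
    data = IncidenceDataset(("a", "b", "c"), np.array([2, 5, 9]),
                            np.array([4.0, 5.0, 6.0]))
    return graph, data


def bym_quadrature_agreement(seed: int = 1,
                             mcmc: MCMCConfig = PRODUCTION_SCALE_INCIDENCE) -> dict:
    """Posterior means of theta from a long MCMC run on the three-area toy
    versus deterministic numerical integration, in Monte-Carlo standard
    errors."""
    graph, data = toy_path3()
    oracle = bym_posterior_means(data, graph)
    draws = fit_bym(data, graph, mcmc=mcmc, seed=seed)
    theta = draws.theta()
    means = theta.mean(axis=0)
    errs = np.array([mcse(theta[:, i]) for i in range(3)])
    z = (means - oracle) / errs
    return {
        "oracle": oracle,
        "mcmc_means": means,
        "mcse": errs,
        "z": z,
        "max_abs_z": float(np.abs(z).max()),
    }


def bym_lattice_recovery(seed: int = 1) -> dict:
    """Credible-interval coverage and rank recovery of a planted
    relative-risk field on a 10x10 lattice with 50 expected cases per
    area."""
    s_sim, s_fit = _subseeds(seed, 2)
    _, graph = make_geography(10, 10, 0, seed=0)
    sim = simulate_incidence(graph, alpha=0.0, sigma_u=0.3, sigma_v=0.1,
                             expected=np.full(100, 50.0), seed=s_sim)
    draws = fit_bym(sim.data, graph, mcmc=DESK_SCALE, seed=s_fit)
    est = summarize_sir(draws)
    covered = int(np.sum((est.lo95 <= sim.theta) & (sim.theta <= est.hi95)))
    rho = float(spearmanr(est.median, sim.theta).statistic)
    return {"covered": covered, "n_areas": 100, "rank_corr": rho}


def null_false_positive_study(seed: int = 1, n_meet_runs: int = 10) -> dict:
    """Null lattice simulation: how often do the smoothed intervals exclude
    1, and does the clustering test stay in the 'none' band?"""
    s_sim, s_fit, s_meet = _subseeds(seed, 3)
    _, graph = make_geography(10, 10, 0, seed=0)
    sim = simulate_incidence(graph, alpha=0.0, sigma_u=0.0, sigma_v=0.0,
                             expected=np.full(100, 50.0), seed=s_sim)
    draws = fit_bym(sim.data, graph, mcmc=DESK_SCALE, seed=s_fit)
    est = summarize_sir(draws)
    excl = float(np.mean((est.hi95 < 1.0) | (est.lo95 > 1.0)))
    O, E = modelled_observed_incidence(est, sim.data.e)
    cats = []
    for k in range(n_meet_runs):
        res = tango_meet(O, E, graph.centroids, n_rep=999, seed=s_meet + k)
        cats.append(res.category)
    return {
        "interval_exclusion_fraction": excl,
        "meet_categories": cats,
        "meet_none_count": cats.count("none"),
        "n_meet_runs": n_meet_runs,
    }


def meet_type_one_error(seed: int = 1, n_datasets: int = 200,
                        n_rep: int = 500) -> dict:
    """Rejection rate of the clustering test at the 0.05 band over
    multinomial null datasets on a 7x7 lattice."""
    _, graph = make_geography(7, 7, 0, seed=0)
    E = np.full(49, 20.0)
    rng = np.random.default_rng(seed)
    sub = _subseeds(seed + 1, n_datasets)
    rejections = 0
    for k in range(n_datasets):
        O = rng.multinomial(int(E.sum()), E / E.sum()).astype(float)
        res = tango_meet(O, E, graph.centroids, n_rep=n_rep, seed=sub[k])
        rejections += res.p < 0.05
    return {"rejections": int(rejections), "n_datasets": n_datasets,
            "rate": rejections / n_datasets}


def _survival_inputs(seed: int, planted_area: int | None, n_cases: int = 20_000):
    s_geo, s_pop, s_sim = _subseeds(seed, 3)
    _, g0 = make_geography(8, 8, 0, seed=s_geo)
    graph, _ = repair_isolates(g0)
    pops, lt = simulate_populations_and_lifetable(graph, seed=s_pop)
    alpha_j = np.log(np.array([0.30, 0.20, 0.12, 0.08, 0.06]))
    beta_k = np.array([0.0, 0.3, 0.6, 1.0])
    log_rer = np.zeros(graph.n_areas)
    if planted_area is not None:
        log_rer[planted_area] = np.log(2.0)  # doubled excess hazard
    sim = simulate_survival_records(
        graph, alpha_j, beta_k, pops, lt, n_cases=n_cases, window=_WINDOW,
        area_log_rer=log_rer, seed=s_sim,
    )
    kept, _ = apply_survival_exclusions(sim.records, _WINDOW)
    cells = collapse_person_time(kept, lt, _WINDOW,
                                 broad_age_groups=DEFAULT_BROAD_AGE_GROUPS,
                                 area_ids=list(graph.area_ids))
    return graph, cells


def survival_recovery_study(seed: int = 1, planted_area: int = 27) -> dict:
    """Planted-signal recovery for the excess-mortality model: one area with
    doubled excess hazard on an 8x8 lattice, 20,000 simulated cases, plus an
    all-null rerun."""
    s_fit, s_fit0 = _subseeds(seed + 17, 2)
    graph, cells = _survival_inputs(seed, planted_area)
    draws = fit_excess_mortality(cells, graph, mcmc=DESK_SCALE, seed=s_fit)
    est = summarize_rer(draws)
    graph0, cells0 = _survival_inputs(seed, None)
    draws0 = fit_excess_mortality(cells0, graph0, mcmc=DESK_SCALE, seed=s_fit0)
    est0 = summarize_rer(draws0)
    return {
        "planted_median": float(est.median[planted_area]),
        "planted_lo95": float(est.lo95[planted_area]),
        "planted_hi95": float(est.hi95[planted_area]),
        "null_median_min": float(est0.median.min()),
        "null_median_max": float(est0.median.max()),
        "n_areas": graph.n_areas,
    }


def adjusted_deaths_identity(seed: int = 1) -> dict:
    """Adjusted deaths equal the RER = 1 expected totals exactly when the
    area components vanish, and collapse to the background totals without
    person-time."""
    graph, cells = _survival_inputs(seed, None, n_cases=2_000)
    state = SurvivalState(
        alpha=np.log(np.array([0.30, 0.20, 0.12, 0.08, 0.06])),
        beta=np.array([0.0, 0.3, 0.6, 1.0]),
        u=np.zeros(graph.n_areas), v=np.zeros(graph.n_areas),
        tau_u=1.0, tau_v=1.0,
    )
    adj, exp_ = adjusted_deaths(state, cells)
    null_err = float(np.abs(adj - exp_).max())
    from .prep import SurvivalCellTable

    no_time = SurvivalCellTable(
        cells.area_ids, cells.age_groups, cells.n_intervals, cells.age_idx,
        cells.interval, cells.area_idx, np.zeros(cells.n_cells), cells.d,
        cells.dstar,
    )
    adj0, _ = adjusted_deaths(state, no_time)
    dstar_totals = np.bincount(cells.area_idx, weights=cells.dstar,
                               minlength=graph.n_areas)
    dstar_err = float(np.abs(adj0 - dstar_totals).max())
    return {"null_identity_error": null_err, "dstar_only_error": dstar_err}


def geweke_calibration(seed: int = 1, n_chains: int = 478,
                       chain_length: int = 10_000) -> dict:
    """Geweke flag rate over iid chains and the degenerate constant-chain
    value."""
    rng = np.random.default_rng(seed)
    flags = sum(
        geweke_z(rng.standard_normal(chain_length)).p < 0.01
        for _ in range(n_chains)
    )
    const = geweke_z(np.full(chain_length, 3.14))
    return {
        "flags": int(flags),
        "n_chains": n_chains,
        "flag_fraction": flags / n_chains,
        "constant_chain_z": const.z,
        "constant_chain_p": const.p,
    }
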