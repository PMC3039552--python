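"""Spatial relative-survival (excess mortality) modelling.

Observed deaths in collapsed cells (k: broad age group, j: follow-up year,
i: area) follow

    d_kji ~ Poisson(mu_kji),
    log(mu_kji - d*_kji) = log(y_kji) + alpha_j + beta_k + u_i + v_i,

where ``y_kji`` is person-time at risk, ``d*_kji`` the expected background
deaths from the population life table, ``alpha_j`` a follow-up-year
intercept, ``beta_k`` broad-age-group coefficients (first group is the
reference, fixed at zero), and ``u``, ``v`` the spatially structured (CAR)
and unstructured area effects.  The area-level relative excess risk is
RER_i = exp(u_i + v_i).  By construction mu exceeds d*, so the excess-hazard
surface is non-negative for every admissible state.

The sampler shares its architecture with the incidence model: single-site
adaptive random-walk updates (alpha_j and beta_k blocks act on disjoint cell
sets, u is updated by graph colour class, v in parallel), sum-to-zero
re-centring of u absorbed into the intercepts, and conjugate Gibbs updates
for Gamma-prior precisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ._samplers import (
    PrecisionUpdater,
    ScaleMove,
    TARGET_ACCEPT,
    icar_quadform,
    rm_step,
)
from .bym import _log_precision_prior
from .config import (
    DEFAULT_SURVIVAL_PRIOR,
    DESK_SCALE,
    MCMCConfig,
    PriorSpec,
)
from .containers import PosteriorDraws, SmoothedEstimates
from .geography import AreaGraph
from .prep import SurvivalCellTable

__all__ = [
    "SurvivalState",
    "log_posterior_excess",
    "fit_excess_mortality",
    "summarize_rer",
    "point_estimates",
    "adjusted_deaths",
]

_SUM_ZERO_TOL = 1e-6


@dataclass(frozen=True)
class SurvivalState:
    """One point in the excess-mortality parameter space; ``beta[0]`` is the
    reference age group and must be zero."""

    alpha: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: float
    tau_v: float

    def __post_init__(self) -> None:
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValueError("precisions must be positive")
        a = np.asarray(self.alpha, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        if b.size and b[0] != 0.0:
            raise ValueError("beta[0] is the reference category and must be 0")
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != v.shape:
            raise ValueError("u and v must be equal-length vectors")
        for name, arr in (("alpha", a), ("beta", b), ("u", u), ("v", v)):
            object.__setattr__(self, name, arr)


def _cell_loglik(d, y, dstar, lp) -> np.ndarray:
    mu = dstar + y * np.exp(lp)
    # link guarantee: mu > dstar whenever y > 0
    assert np.all(mu > dstar)
    return d * np.log(mu) - mu - gammaln(d + 1)


def log_posterior_excess(
    state: SurvivalState,
    cells: SurvivalCellTable,
    graph: AreaGraph,
    priors: PriorSpec = DEFAULT_SURVIVAL_PRIOR,
) -> float:
    """Unnormalised log posterior of the spatial excess-mortality model.

    All cells entering the likelihood must carry positive person-time; cells
    with negative expected background deaths are rejected.
    """
    if cells.n_areas != graph.n_areas or len(state.u) != graph.n_areas:
        raise ValueError("state, cells and graph dimensions disagree")
    if len(state.alpha) < cells.n_intervals:
        raise ValueError("alpha has fewer entries than follow-up intervals")
    if len(state.beta) < len(cells.age_groups):
        raise ValueError("beta has fewer entries than broad age groups")
    if np.any(cells.dstar < 0):
        raise ValueError("negative expected background deaths")
    if np.any(cells.y <= 0):
        raise ValueError("cells entering the likelihood need positive person-time")
    if abs(float(np.sum(state.u))) > _SUM_ZERO_TOL * max(
        1.0, float(np.abs(state.u).max(initial=0.0)) * len(state.u)
    ):
        raise ValueError("u violates the sum-to-zero constraint")
    lp = (
        state.alpha[cells.interval - 1]
        + state.beta[cells.age_idx]
        + state.u[cells.area_idx]
        + state.v[cells.area_idx]
    )
    loglik = float(np.sum(_cell_loglik(cells.d, cells.y, cells.dstar, lp)))
    edges = graph.edges()
    rank = graph.n_areas - graph.n_components()
    q = icar_quadform(state.u, edges)
    log_icar = (rank / 2) * math.log(state.tau_u) - state.tau_u * q / 2
    n = graph.n_areas
    log_v = (n / 2) * math.log(state.tau_v) - state.tau_v * float(state.v @ state.v) / 2 \
        - (n / 2) * math.log(2 * math.pi)
    var_a = priors.alpha_variance
    free_coef = np.concatenate([state.alpha, state.beta[1:]])
    log_coef = float(
        np.sum(-0.5 * free_coef**2 / var_a - 0.5 * math.log(2 * math.pi * var_a))
    )
    log_hyper = _log_precision_prior(state.tau_u, priors.tau_u) + \
        _log_precision_prior(state.tau_v, priors.tau_v)
    return loglik + log_icar + log_v + log_coef + log_hyper


def fit_excess_mortality(
    cells: SurvivalCellTable,
    graph: AreaGraph,
    priors: PriorSpec = DEFAULT_SURVIVAL_PRIOR,
    mcmc: MCMCConfig = DESK_SCALE,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the spatial excess-mortality model by single-chain MCMC;
    deterministic given ``seed``.  Sexes are fitted separately by the caller.
    """
    if cells.n_areas != graph.n_areas:
        raise ValueError("cells and graph dimensions disagree")
    if graph.isolates():
        raise ValueError("graph has isolates; repair it first")
    if np.any(cells.y <= 0):
        raise ValueError("drop zero person-time cells before fitting")
    n = graph.n_areas
    n_j = cells.n_intervals
    n_k = len(cells.age_groups)
    jix = cells.interval - 1
    kix = cells.age_idx
    iix = cells.area_idx
    y, d, dstar = cells.y, cells.d.astype(float), cells.dstar
    edges = graph.edges()
    deg = graph.degrees.astype(float)
    w = graph.adjacency_matrix()
    colours = graph.colour_classes()
    rank = n - graph.n_components()
    rng = np.random.default_rng(seed)
    var_a = priors.alpha_variance

    # crude initial excess-hazard level from the pooled data
    excess0 = max(float(d.sum() - dstar.sum()), 0.5) / float(y.sum())
    alpha = np.full(n_j, math.log(excess0))
    beta = np.zeros(n_k)
    u = np.zeros(n)
    v = np.zeros(n)
    upd_tau_u = PrecisionUpdater(priors.tau_u, rank)
    upd_tau_v = PrecisionUpdater(priors.tau_v, n)
    tau_u = upd_tau_u.initial_tau()
    tau_v = upd_tau_v.initial_tau()

    ls_a = np.full(n_j, math.log(0.2))
    ls_b = np.full(n_k, math.log(0.2))
    ls_u = np.full(n, math.log(0.5))
    ls_v = np.full(n, math.log(0.5))
    scale_u = ScaleMove(priors.tau_u)
    scale_v = ScaleMove(priors.tau_v)

    # cell masks per colour class for the u updates
    colour_of = np.empty(n, dtype=int)
    for c, idx in enumerate(colours):
        colour_of[idx] = c
    cell_colour = colour_of[iix]
    cell_sets = [np.nonzero(cell_colour == c)[0] for c in range(len(colours))]

    def loglik_cells(sel, lp_sel):
        mu = dstar[sel] + y[sel] * np.exp(lp_sel)
        return d[sel] * np.log(mu) - mu

    n_draws = mcmc.n_draws
    out = {
        "alpha": np.empty((n_draws, n_j)),
        "beta": np.empty((n_draws, n_k)),
        "u": np.empty((n_draws, n)),
        "v": np.empty((n_draws, n)),
        "tau_u": np.empty(n_draws),
        "tau_v": np.empty(n_draws),
    }
    store = 0
    total = mcmc.burn_in + mcmc.kept
    # extreme rejected proposals may overflow exp(); they resolve to -inf
    # or nan acceptance ratios and are rejected, so warnings are suppressed
    old_err = np.seterr(over="ignore", invalid="ignore")
    for it in range(total):
        adapting = it < mcmc.burn_in
        gain = rm_step(it) if adapting else 0.0

        lp = alpha[jix] + beta[kix] + u[iix] + v[iix]
        ll_cur = loglik_cells(slice(None), lp)

        # alpha_j: disjoint cell sets, updated in parallel
        prop_a = alpha + np.exp(ls_a) * rng.standard_normal(n_j)
        lp_new = lp + (prop_a - alpha)[jix]
        dll = np.bincount(jix, weights=loglik_cells(slice(None), lp_new) - ll_cur,
                          minlength=n_j)
        dll += -(prop_a**2 - alpha**2) / (2 * var_a)
        acc = np.log(rng.uniform(size=n_j)) < dll
        alpha[acc] = prop_a[acc]
        if adapting:
            ls_a += gain * (acc - TARGET_ACCEPT)
        lp = alpha[jix] + beta[kix] + u[iix] + v[iix]
        ll_cur = loglik_cells(slice(None), lp)

        # beta_k (k >= 1): disjoint cell sets, updated in parallel
        if n_k > 1:
            prop_b = beta + np.exp(ls_b) * rng.standard_normal(n_k)
            prop_b[0] = 0.0
            lp_new = lp + (prop_b - beta)[kix]
            dll = np.bincount(kix, weights=loglik_cells(slice(None), lp_new) - ll_cur,
                              minlength=n_k)
            dll += -(prop_b**2 - beta**2) / (2 * var_a)
            acc = np.log(rng.uniform(size=n_k)) < dll
            acc[0] = False
            beta[acc] = prop_b[acc]
            if adapting:
                ls_b[1:] += gain * (acc[1:] - TARGET_ACCEPT)
            lp = alpha[jix] + beta[kix] + u[iix] + v[iix]
            ll_cur = loglik_cells(slice(None), lp)

        # u: single-site MH by colour class
        for c, idx in enumerate(colours):
            s_nb = np.asarray(w @ u)[idx]
            cur = u[idx]
            prop_u = cur + np.exp(ls_u[idx]) * rng.standard_normal(len(idx))
            sel = cell_sets[c]
            delta = np.zeros(n)
            delta[idx] = prop_u - cur
            dll_cells = loglik_cells(sel, lp[sel] + delta[iix[sel]]) - ll_cur[sel]
            dll_area = np.bincount(iix[sel], weights=dll_cells, minlength=n)[idx]
            d_pri = -tau_u / 2 * (
                deg[idx] * (prop_u**2 - cur**2) - 2 * s_nb * (prop_u - cur)
            )
            acc_m = np.log(rng.uniform(size=len(idx))) < dll_area + d_pri
            changed = idx[acc_m]
            u[changed] = prop_u[acc_m]
            if adapting:
                ls_u[idx] += gain * (acc_m - TARGET_ACCEPT)
            if len(changed):
                sel_changed = sel[np.isin(iix[sel], changed)]
                lp[sel_changed] = (
                    alpha[jix[sel_changed]] + beta[kix[sel_changed]]
                    + u[iix[sel_changed]] + v[iix[sel_changed]]
                )
                ll_cur[sel_changed] = loglik_cells(sel_changed, lp[sel_changed])
        # sum-to-zero re-centring, shift absorbed into the intercepts
        shift = float(u.mean())
        u -= shift
        alpha += shift
        lp = alpha[jix] + beta[kix] + u[iix] + v[iix]
        ll_cur = loglik_cells(slice(None), lp)

        # v: all areas conditionally independent
        prop_v = v + np.exp(ls_v) * rng.standard_normal(n)
        lp_new = lp + (prop_v - v)[iix]
        dll_area = np.bincount(
            iix, weights=loglik_cells(slice(None), lp_new) - ll_cur, minlength=n
        )
        dll_area += -tau_v / 2 * (prop_v**2 - v**2)
        acc_m = np.log(rng.uniform(size=n)) < dll_area
        v[acc_m] = prop_v[acc_m]
        if adapting:
            ls_v += gain * (acc_m - TARGET_ACCEPT)

        # precisions
        tau_u = upd_tau_u.draw(rng, tau_u, icar_quadform(u, edges), adapting, gain)
        tau_v = upd_tau_v.draw(rng, tau_v, float(v @ v), adapting, gain)

        # interweaving scale moves across the (tau, effects) funnels;
        # overflowing proposals evaluate to -inf and are rejected
        lp = alpha[jix] + beta[kix] + u[iix] + v[iix]
        ll_tot = float(loglik_cells(slice(None), lp).sum())
        with np.errstate(over="ignore", invalid="ignore"):
            for vec, scl, tau_cur in (("u", scale_u, None), ("v", scale_v, None)):
                delta = scl.propose(rng)
                if vec == "u":
                    x_p = u * math.exp(-delta / 2)
                    tau_p = tau_u * math.exp(delta)
                    tau_old = tau_u
                    lp_p = alpha[jix] + beta[kix] + x_p[iix] + v[iix]
                else:
                    x_p = v * math.exp(-delta / 2)
                    tau_p = tau_v * math.exp(delta)
                    tau_old = tau_v
                    lp_p = alpha[jix] + beta[kix] + u[iix] + x_p[iix]
                ll_p = float(loglik_cells(slice(None), lp_p).sum())
                logr = ll_p - ll_tot + scl.log_prior_term(tau_p) \
                    - scl.log_prior_term(tau_old)
                acc = not math.isnan(logr) and math.log(rng.uniform()) < logr
                if acc:
                    if vec == "u":
                        u, tau_u = x_p, tau_p
                    else:
                        v, tau_v = x_p, tau_p
                    lp = lp_p
                    ll_tot = ll_p
                if adapting:
                    scl.adapt(acc, gain)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == mcmc.thin - 1:
            out["alpha"][store] = alpha
            out["beta"][store] = beta
            out["u"][store] = u
            out["v"][store] = v
            out["tau_u"][store] = tau_u
            out["tau_v"][store] = tau_v
            store += 1
    np.seterr(**old_err)
    assert store == n_draws
    return PosteriorDraws(
        kind="survival",
        area_ids=graph.area_ids,
        params=out,
        config=mcmc,
        seed=seed,
    )


def summarize_rer(draws: PosteriorDraws) -> SmoothedEstimates:
    """Per-area posterior median RER = exp(u_i + v_i) with central 95%
    credible interval and map category."""
    from .mapping import categorize_for_map

    rer = draws.rer()
    if rer.shape[0] == 0:
        raise ValueError("empty draws")
    med = np.median(rer, axis=0)
    lo, hi = np.percentile(rer, [2.5, 97.5], axis=0)
    cats = tuple(categorize_for_map(m) for m in med)
    return SmoothedEstimates(draws.area_ids, med, lo, hi, cats, measure="rer")


def point_estimates(draws: PosteriorDraws) -> SurvivalState:
    """Posterior-median parameter point (the default input to the clustering
    test's adjusted-deaths calculation)."""
    if draws.kind != "survival":
        raise ValueError("point_estimates expects survival draws")
    beta = np.median(draws.params["beta"], axis=0)
    beta[0] = 0.0
    return SurvivalState(
        alpha=np.median(draws.params["alpha"], axis=0),
        beta=beta,
        u=np.median(draws.params["u"], axis=0),
        v=np.median(draws.params["v"], axis=0),
        tau_u=float(np.median(draws.params["tau_u"])),
        tau_v=float(np.median(draws.params["tau_v"])),
    )


def adjusted_deaths(
    state: SurvivalState, cells: SurvivalCellTable
) -> tuple[np.ndarray, np.ndarray]:
    """Per-area adjusted and expected death totals.

    Adjusted: A_i = sum_kj [ y_kji e^{alpha_j} e^{beta_k} RER_i + d*_kji ];
    expected: the same with RER_i set to 1.  A equals E exactly when every
    u_i + v_i is zero.
    """
    n = cells.n_areas
    base = cells.y * np.exp(state.alpha[cells.interval - 1] + state.beta[cells.age_idx])
    rer = np.exp(state.u + state.v)
    adj = np.bincount(cells.area_idx, weights=base * rer[cells.area_idx], minlength=n)
    exp_ = np.bincount(cells.area_idx, weights=base, minlength=n)
    ds = np.bincount(cells.area_idx, weights=cells.dstar, minlength=n)
    return adj + ds, exp_ + ds
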