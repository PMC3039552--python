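"""Besag-York-Mollie smoothing of small-area incidence.

The model for area counts is

    y_i ~ Poisson(e_i * theta_i),    log(theta_i) = alpha + u_i + v_i,

with ``alpha`` the overall log relative risk (vague normal prior), ``u`` a
spatially structured effect under an intrinsic conditional-autoregressive
(CAR) prior on the area adjacency graph, and ``v`` iid normal unstructured
heterogeneity.  The intrinsic CAR joint density is, up to a constant,
exp(-tau_u/2 * sum_{i~j} (u_i - u_j)^2) on the sum-to-zero subspace;
equivalently each u_i is conditionally normal around its neighbour mean with
precision tau_u * n_i.  Precisions tau_u, tau_v carry the configured
hyperpriors.

Fitting is by single-chain Metropolis-within-Gibbs with single-site
random-walk updates vectorised over conditionally independent colour classes
of the graph, sum-to-zero re-centring of u absorbed into alpha every sweep,
and conjugate Gibbs draws for Gamma-prior precisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from ._samplers import (
    PrecisionUpdater,
    ScalarAdaptiveMH,
    ScaleMove,
    TARGET_ACCEPT,
    icar_quadform,
    rm_step,
)
from .config import (
    DEFAULT_INCIDENCE_PRIOR,
    DESK_SCALE,
    GammaPrior,
    MCMCConfig,
    PriorSpec,
)
from .containers import IncidenceDataset, PosteriorDraws, SmoothedEstimates
from .geography import AreaGraph

__all__ = [
    "BYMState",
    "log_posterior_bym",
    "fit_bym",
    "summarize_sir",
    "model_fit_stats",
]

_SUM_ZERO_TOL = 1e-6


@dataclass(frozen=True)
class BYMState:
    """One point in the BYM parameter space."""

    alpha: float
    u: np.ndarray
    v: np.ndarray
    tau_u: float
    tau_v: float

    def __post_init__(self) -> None:
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValueError("precisions must be positive")
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != v.shape or u.ndim != 1:
            raise ValueError("u and v must be equal-length vectors")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)


def _log_precision_prior(tau: float, prior) -> float:
    if isinstance(prior, GammaPrior):
        return float(gamma_dist.logpdf(tau, prior.shape, scale=1.0 / prior.rate))
    # uniform on sigma transformed to the tau scale:
    # p(tau) = 1/(hi-lo) * 1/2 * tau^(-3/2) for sigma = tau^(-1/2) in (lo, hi)
    sigma = tau**-0.5
    if not (prior.lo < sigma < prior.hi):
        return -math.inf
    return -math.log(prior.hi - prior.lo) + math.log(0.5) - 1.5 * math.log(tau)


def log_posterior_bym(
    state: BYMState,
    data: IncidenceDataset,
    graph: AreaGraph,
    priors: PriorSpec = DEFAULT_INCIDENCE_PRIOR,
) -> float:
    """Unnormalised log posterior density of the BYM model.

    The intrinsic CAR term contributes (rank/2) log tau_u - tau_u/2 * Q(u)
    with Q the sum of squared neighbour differences and rank = n - number of
    graph components; the state must satisfy the sum-to-zero constraint on u
    (per connected graph the constraint is global; violation beyond tolerance
    is rejected).
    """
    if len(state.u) != data.n_areas or data.n_areas != graph.n_areas:
        raise ValueError("state, data and graph dimensions disagree")
    if abs(float(np.sum(state.u))) > _SUM_ZERO_TOL * max(
        1.0, float(np.abs(state.u).max(initial=0.0)) * len(state.u)
    ):
        raise ValueError("u violates the sum-to-zero constraint")
    y, e = data.y, data.e
    eta = state.alpha + state.u + state.v
    lam = e * np.exp(eta)
    if np.any(lam <= 0):
        raise ValueError("expected counts must be positive")
    loglik = float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))
    edges = graph.edges()
    rank = graph.n_areas - graph.n_components()
    q = icar_quadform(state.u, edges)
    log_icar = (rank / 2) * math.log(state.tau_u) - state.tau_u * q / 2
    n = graph.n_areas
    sv2 = float(state.v @ state.v)
    log_v = (n / 2) * math.log(state.tau_v) - state.tau_v * sv2 / 2 \
        - (n / 2) * math.log(2 * math.pi)
    log_alpha = -0.5 * state.alpha**2 / priors.alpha_variance \
        - 0.5 * math.log(2 * math.pi * priors.alpha_variance)
    log_hyper = _log_precision_prior(state.tau_u, priors.tau_u) + \
        _log_precision_prior(state.tau_v, priors.tau_v)
    return loglik + log_icar + log_v + log_alpha + log_hyper


def fit_bym(
    data: IncidenceDataset,
    graph: AreaGraph,
    priors: PriorSpec = DEFAULT_INCIDENCE_PRIOR,
    mcmc: MCMCConfig = DESK_SCALE,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit the BYM model by single-chain MCMC; deterministic given ``seed``.

    Requires an isolate-free graph and strictly positive expected counts.
    Update order per sweep: alpha, u (by colour class, then re-centred with
    the shift absorbed into alpha), v, tau_u, tau_v.
    """
    if data.n_areas != graph.n_areas:
        raise ValueError("data and graph dimensions disagree")
    if graph.isolates():
        raise ValueError("graph has isolates; repair it first")
    if np.any(data.e <= 0):
        raise ValueError("zero expected counts: every area needs e_i > 0")
    n = graph.n_areas
    y, e = data.y, data.e
    edges = graph.edges()
    deg = graph.degrees.astype(float)
    w = graph.adjacency_matrix()
    colours = graph.colour_classes()
    rank = n - graph.n_components()
    rng = np.random.default_rng(seed)

    alpha = math.log(max(y.sum(), 0.5) / e.sum())
    u = np.zeros(n)
    v = np.zeros(n)
    upd_tau_u = PrecisionUpdater(priors.tau_u, rank)
    upd_tau_v = PrecisionUpdater(priors.tau_v, n)
    tau_u = upd_tau_u.initial_tau()
    tau_v = upd_tau_v.initial_tau()

    alpha_mh = ScalarAdaptiveMH(0.1)
    ls_u = np.full(n, math.log(0.5))
    ls_v = np.full(n, math.log(0.5))
    scale_u = ScaleMove(priors.tau_u)
    scale_v = ScaleMove(priors.tau_v)

    n_draws = mcmc.n_draws
    out = {
        "alpha": np.empty(n_draws),
        "u": np.empty((n_draws, n)),
        "v": np.empty((n_draws, n)),
        "tau_u": np.empty(n_draws),
        "tau_v": np.empty(n_draws),
    }
    y_sum = float(y.sum())
    store = 0
    total = mcmc.burn_in + mcmc.kept
    # extreme rejected proposals may overflow exp(); they resolve to -inf
    # acceptance ratios, so the warnings are suppressed for the whole run
    old_err = np.seterr(over="ignore")
    for it in range(total):
        adapting = it < mcmc.burn_in
        gain = rm_step(it) if adapting else 0.0

        # alpha: scalar random-walk MH
        prop = alpha_mh.propose(rng, alpha)
        s_uv = float(np.sum(e * np.exp(u + v)))
        logr = (prop - alpha) * y_sum - (math.exp(prop) - math.exp(alpha)) * s_uv \
            - (prop**2 - alpha**2) / (2 * priors.alpha_variance)
        acc = math.log(rng.uniform()) < logr
        if acc:
            alpha = prop
        if adapting:
            alpha_mh.adapt(acc, gain)

        # u: single-site MH vectorised over colour classes
        for idx in colours:
            s_nb = np.asarray(w @ u)[idx]
            cur = u[idx]
            prop_u = cur + np.exp(ls_u[idx]) * rng.standard_normal(len(idx))
            lam_base = e[idx] * np.exp(alpha + v[idx])
            d_lik = y[idx] * (prop_u - cur) - lam_base * (np.exp(prop_u) - np.exp(cur))
            d_pri = -tau_u / 2 * (
                deg[idx] * (prop_u**2 - cur**2) - 2 * s_nb * (prop_u - cur)
            )
            acc_m = np.log(rng.uniform(size=len(idx))) < d_lik + d_pri
            u[idx[acc_m]] = prop_u[acc_m]
            if adapting:
                ls_u[idx] += gain * (acc_m - TARGET_ACCEPT)
        # sum-to-zero re-centring, shift absorbed into alpha
        shift = float(u.mean())
        u -= shift
        alpha += shift

        # v: all sites conditionally independent
        prop_v = v + np.exp(ls_v) * rng.standard_normal(n)
        lam_base = e * np.exp(alpha + u)
        d = y * (prop_v - v) - lam_base * (np.exp(prop_v) - np.exp(v)) \
            - tau_v / 2 * (prop_v**2 - v**2)
        acc_m = np.log(rng.uniform(size=n)) < d
        v[acc_m] = prop_v[acc_m]
        if adapting:
            ls_v += gain * (acc_m - TARGET_ACCEPT)

        # precisions
        tau_u = upd_tau_u.draw(rng, tau_u, icar_quadform(u, edges), adapting, gain)
        tau_v = upd_tau_v.draw(rng, tau_v, float(v @ v), adapting, gain)

        # interweaving scale moves across the (tau, effects) funnels;
        # overflowing proposals evaluate to -inf and are rejected
        with np.errstate(over="ignore"):
            delta = scale_u.propose(rng)
            u_p = u * math.exp(-delta / 2)
            tau_p = tau_u * math.exp(delta)
            lam_base = e * np.exp(alpha + v)
            logr = float(np.sum(y * (u_p - u) - lam_base * (np.exp(u_p) - np.exp(u)))) \
                + scale_u.log_prior_term(tau_p) - scale_u.log_prior_term(tau_u)
            acc = not math.isnan(logr) and math.log(rng.uniform()) < logr
            if acc:
                u, tau_u = u_p, tau_p
            if adapting:
                scale_u.adapt(acc, gain)

            delta = scale_v.propose(rng)
            v_p = v * math.exp(-delta / 2)
            tau_p = tau_v * math.exp(delta)
            lam_base = e * np.exp(alpha + u)
            logr = float(np.sum(y * (v_p - v) - lam_base * (np.exp(v_p) - np.exp(v)))) \
                + scale_v.log_prior_term(tau_p) - scale_v.log_prior_term(tau_v)
            acc = not math.isnan(logr) and math.log(rng.uniform()) < logr
            if acc:
                v, tau_v = v_p, tau_p
            if adapting:
                scale_v.adapt(acc, gain)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == mcmc.thin - 1:
            out["alpha"][store] = alpha
            out["u"][store] = u
            out["v"][store] = v
            out["tau_u"][store] = tau_u
            out["tau_v"][store] = tau_v
            store += 1
    np.seterr(**old_err)
    assert store == n_draws
    return PosteriorDraws(
        kind="incidence",
        area_ids=graph.area_ids,
        params=out,
        config=mcmc,
        seed=seed,
    )


def summarize_sir(draws: PosteriorDraws) -> SmoothedEstimates:
    """Per-area posterior median SIR with central 95% credible interval and
    map category (ratio scale; multiply by 100 for display)."""
    from .mapping import categorize_for_map

    theta = draws.theta()
    if theta.shape[0] == 0:
        raise ValueError("empty draws")
    med = np.median(theta, axis=0)
    lo, hi = np.percentile(theta, [2.5, 97.5], axis=0)
    cats = tuple(categorize_for_map(m) for m in med)
    return SmoothedEstimates(draws.area_ids, med, lo, hi, cats, measure="sir")


def _poisson_deviance(y, e, alpha, u, v) -> float:
    lam = e * np.exp(alpha + u + v)
    return -2.0 * float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))


def model_fit_stats(
    draws: PosteriorDraws, data: IncidenceDataset, graph: AreaGraph
) -> dict[str, float]:
    """Model comparison summaries used by the prior sensitivity analysis.

    - pD: mean posterior deviance minus the deviance at the posterior means
      of (alpha, u, v); DIC = mean deviance + pD.
    - spatial_fraction: posterior mean of sd(u) / (sd(u) + sd(v)) across the
      empirical marginal spread of the two random-effect vectors per draw.
    - ratio90: 95th over 5th percentile of the per-area posterior-median SIR.
    """
    theta = draws.theta()
    a = draws.params["alpha"]
    u = draws.params["u"]
    v = draws.params["v"]
    y, e = data.y, data.e
    dev = np.array([
        _poisson_deviance(y, e, a[t], u[t], v[t]) for t in range(len(a))
    ])
    dev_at_mean = _poisson_deviance(
        y, e, float(a.mean()), u.mean(axis=0), v.mean(axis=0)
    )
    p_d = float(dev.mean() - dev_at_mean)
    dic = float(dev.mean() + p_d)
    sd_u = u.std(axis=1)
    sd_v = v.std(axis=1)
    denom = sd_u + sd_v
    frac = np.where(denom > 0, sd_u / np.where(denom > 0, denom, 1.0), 0.0)
    med = np.median(theta, axis=0)
    q5, q95 = np.percentile(med, [5, 95])
    ratio90 = float(q95 / q5) if q5 > 0 else math.inf
    return {
        "pD": p_d,
        "DIC": dic,
        "spatial_fraction": float(frac.mean()),
        "ratio90": ratio90,
    }
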