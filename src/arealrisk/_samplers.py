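"""Internal Metropolis-within-Gibbs building blocks shared by the incidence
and survival samplers.

Single-site random-walk proposals are adapted during burn-in by Robbins-Monro
steps on the log proposal scale toward a 44% acceptance rate, then frozen.
Precision parameters with Gamma priors are updated by conjugate Gibbs draws;
uniform-on-sigma priors fall back to a random-walk on log(tau).
"""

from __future__ import annotations

import math

import numpy as np

from .config import GammaPrior, UniformSigmaPrior

TARGET_ACCEPT = 0.44


def rm_step(iteration: int) -> float:
    """Robbins-Monro gain at a given (0-based) iteration."""
    return (iteration + 1) ** -0.6


class PrecisionUpdater:
    """Gibbs (gamma prior) or adaptive log-scale MH (uniform-on-sigma prior)
    update for a precision tau given its Gaussian quadratic form.

    The conditional density of tau given the field is proportional to
    tau^(dims/2) * exp(-tau * quad / 2) * prior(tau), where ``dims`` is the
    rank of the Gaussian (n - #components for the intrinsic CAR field, n for
    iid effects) and ``quad`` the sum of squared increments / values.
    """

    def __init__(self, prior: GammaPrior | UniformSigmaPrior, dims: int):
        self.prior = prior
        self.dims = dims
        self.log_scale = math.log(0.5)

    def initial_tau(self) -> float:
        if isinstance(self.prior, GammaPrior):
            return min(max(self.prior.shape / self.prior.rate, 1e-2), 1e2)
        sigma = 0.5 * (self.prior.lo + self.prior.hi)
        if sigma <= 0:
            sigma = 0.5
        return min(1.0 / sigma**2, 1e2)

    def _log_target(self, phi: float, quad: float) -> float:
        # phi = log(tau); includes the log-jacobian of the transform.
        tau = math.exp(phi)
        sigma = tau**-0.5
        if not (self.prior.lo < sigma < self.prior.hi):
            return -math.inf
        return (self.dims / 2) * phi - tau * quad / 2 - 1.5 * phi + phi

    def draw(
        self, rng: np.random.Generator, tau: float, quad: float, adapting: bool,
        gain: float,
    ) -> float:
        if isinstance(self.prior, GammaPrior):
            shape = self.prior.shape + self.dims / 2
            rate = self.prior.rate + quad / 2
            return float(rng.gamma(shape, 1.0 / rate))
        phi = math.log(tau)
        prop = phi + math.exp(self.log_scale) * rng.standard_normal()
        logr = self._log_target(prop, quad) - self._log_target(phi, quad)
        accept = math.log(rng.uniform()) < logr
        if adapting:
            self.log_scale += gain * ((1.0 if accept else 0.0) - TARGET_ACCEPT)
        return math.exp(prop) if accept else tau


class ScalarAdaptiveMH:
    """Adaptive random-walk proposal state for a scalar parameter."""

    def __init__(self, init_scale: float = 0.1):
        self.log_scale = math.log(init_scale)

    def propose(self, rng: np.random.Generator, current: float) -> float:
        return current + math.exp(self.log_scale) * rng.standard_normal()

    def adapt(self, accepted: bool, gain: float) -> None:
        self.log_scale += gain * ((1.0 if accepted else 0.0) - TARGET_ACCEPT)


class ScaleMove:
    """Interweaving rescaling of a random-effect vector and its precision.

    Gamma-type hyperpriors on a precision induce a funnel between tau and
    the effect vector that single-site updates traverse slowly.  This move
    proposes tau' = tau * e^delta, x' = x * e^(-delta/2), which keeps the
    standardised effects x * sqrt(tau) fixed; in those coordinates the
    Gaussian prior and Jacobian cancel, so the acceptance ratio reduces to
    the likelihood ratio times p(tau') e^(log tau') / (p(tau) e^(log tau)).
    """

    def __init__(self, prior, init_scale: float = 0.5):
        self.prior = prior
        self.log_scale = math.log(init_scale)

    def log_prior_term(self, tau: float) -> float:
        if isinstance(self.prior, GammaPrior):
            return self.prior.shape * math.log(tau) - self.prior.rate * tau
        sigma = tau**-0.5
        if not (self.prior.lo < sigma < self.prior.hi):
            return -math.inf
        return -0.5 * math.log(tau)

    def propose(self, rng: np.random.Generator) -> float:
        return math.exp(self.log_scale) * rng.standard_normal()

    def adapt(self, accepted: bool, gain: float) -> None:
        self.log_scale += gain * ((1.0 if accepted else 0.0) - TARGET_ACCEPT)


def icar_quadform(u: np.ndarray, edges: np.ndarray) -> float:
    """Sum over adjacent pairs of (u_i - u_j)^2, each edge counted once."""
    if len(edges) == 0:
        return 0.0
    d = u[edges[:, 0]] - u[edges[:, 1]]
    return float(d @ d)
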