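"""Model configuration: hyperprior presets, MCMC schedules, diagnostic and
map-classification constants.

The defaults reproduce the analytical configuration of a state-wide
cancer-atlas workflow: a single MCMC chain with a long burn-in and 1-in-10
thinning, Gamma hyperpriors on the precisions of the spatial (CAR) and
unstructured random effects, Geweke screening of every area-level estimate at
p < 0.01, five symmetric map classes cut at 10% and 30% above/below the
regional average, and the 0.01/0.05/0.10 evidence bands for the global
clustering test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = [
    "GammaPrior",
    "UniformSigmaPrior",
    "PriorSpec",
    "MCMCConfig",
    "INCIDENCE_PRIORS",
    "SURVIVAL_PRIORS",
    "DEFAULT_INCIDENCE_PRIOR",
    "DEFAULT_SURVIVAL_PRIOR",
    "PRODUCTION_SCALE_INCIDENCE",
    "PRODUCTION_SCALE_SURVIVAL",
    "DESK_SCALE",
    "GEWEKE_FIRST_N",
    "GEWEKE_LAST_N",
    "GEWEKE_ALPHA",
    "PLOT_SAMPLE_FRACTION",
    "MAP_CUTOFFS",
    "EVIDENCE_BANDS",
    "N_STABILITY_RUNS",
    "DEFAULT_BROAD_AGE_GROUPS",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior on a precision parameter tau."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("Gamma prior parameters must be positive")


@dataclass(frozen=True)
class UniformSigmaPrior:
    """Uniform(lo, hi) prior on the standard deviation sigma = 1/sqrt(tau)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError("Uniform sigma prior bounds must satisfy 0 <= lo < hi")


PrecisionPrior = Union[GammaPrior, UniformSigmaPrior]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors for one model fit.

    ``alpha_variance`` is the variance of the mean-zero normal prior on the
    intercept(s): 1e10 for the incidence model's single intercept, 1e6 for the
    survival model's follow-up-year intercepts and age-group coefficients.
    """

    tau_u: PrecisionPrior
    tau_v: PrecisionPrior
    alpha_variance: float

    def __post_init__(self) -> None:
        if self.alpha_variance <= 0:
            raise ValueError("alpha_variance must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Single-chain Metropolis-within-Gibbs schedule.

    ``burn_in`` iterations are discarded, then ``kept`` further iterations are
    run of which every ``thin``-th is stored, so ``kept // thin`` draws are
    retained.
    """

    burn_in: int
    kept: int
    thin: int

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.kept <= 0 or self.thin <= 0:
            raise ValueError("MCMC settings must be positive")
        if self.kept % self.thin != 0:
            raise ValueError("kept must be a multiple of thin")

    @property
    def n_draws(self) -> int:
        return self.kept // self.thin


# Candidate hyperpriors compared in the incidence sensitivity analysis;
# preset 3 is the production default.
INCIDENCE_PRIORS: dict[int, PriorSpec] = {
    1: PriorSpec(GammaPrior(0.5, 0.0005), GammaPrior(0.5, 0.0005), 1e10),
    2: PriorSpec(GammaPrior(1.0, 1.0), GammaPrior(7.801, 2.793), 1e10),
    3: PriorSpec(GammaPrior(0.1, 0.1), GammaPrior(0.001, 0.001), 1e10),
    4: PriorSpec(GammaPrior(0.1, 0.01), GammaPrior(0.1, 0.01), 1e10),
    5: PriorSpec(UniformSigmaPrior(0.0, 1.0), UniformSigmaPrior(0.0, 1.0), 1e10),
    6: PriorSpec(UniformSigmaPrior(0.0, 1000.0), UniformSigmaPrior(0.0, 1000.0), 1e10),
}

# Candidate hyperpriors for the spatial relative-survival model; preset 3 is
# the production default (best convergence across cancers).
SURVIVAL_PRIORS: dict[int, PriorSpec] = {
    1: PriorSpec(GammaPrior(0.5, 0.001), GammaPrior(0.5, 0.001), 1e6),
    2: PriorSpec(GammaPrior(0.1, 0.1), GammaPrior(0.001, 0.001), 1e6),
    3: PriorSpec(GammaPrior(0.1, 0.01), GammaPrior(0.1, 0.01), 1e6),
    4: PriorSpec(GammaPrior(0.5, 0.0005), GammaPrior(0.5, 0.0005), 1e6),
    5: PriorSpec(UniformSigmaPrior(0.0, 1.0), UniformSigmaPrior(0.0, 1.0), 1e6),
    6: PriorSpec(UniformSigmaPrior(0.0, 1000.0), UniformSigmaPrior(0.0, 1000.0), 1e6),
}

DEFAULT_INCIDENCE_PRIOR = INCIDENCE_PRIORS[3]
DEFAULT_SURVIVAL_PRIOR = SURVIVAL_PRIORS[3]

# Production-scale schedules: 100k burn-in (incidence) / 250k (survival),
# 100k further iterations, 1-in-10 thinning, one chain.
PRODUCTION_SCALE_INCIDENCE = MCMCConfig(burn_in=100_000, kept=100_000, thin=10)
PRODUCTION_SCALE_SURVIVAL = MCMCConfig(burn_in=250_000, kept=100_000, thin=10)
# Reduced schedule for interactive work and simulation studies.
DESK_SCALE = MCMCConfig(burn_in=5_000, kept=5_000, thin=5)

# Geweke screening: first 1000 (10%) vs final 5000 (50%) of the kept draws.
GEWEKE_FIRST_N = 1000
GEWEKE_LAST_N = 5000
GEWEKE_ALPHA = 0.01
# Trace/density/autocorrelation data are emitted for 5% of areas.
PLOT_SAMPLE_FRACTION = 0.05

# Five map classes cut at 10% and 30% above the regional average and the
# inverses below it.
MAP_CUTOFFS = (1 / 1.3, 1 / 1.1, 1.1, 1.3)

# Evidence bands for the global clustering test's adjusted p-value.
EVIDENCE_BANDS = (0.01, 0.05, 0.10)
# The clustering test is repeated a further 5 times (6 total); disagreement is
# resolved to the less significant category.
N_STABILITY_RUNS = 6

# Default broad age groups (by age at diagnosis) for the survival model's
# age coefficients; lower bounds, first group is the reference.
DEFAULT_BROAD_AGE_GROUPS = (0, 60, 70, 80)
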