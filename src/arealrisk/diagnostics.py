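"""Single-chain convergence screening.

The Geweke diagnostic compares the mean of an early window of the kept
(post-thinning) chain with the mean of a late window, standardised by the
asymptotic standard error of the difference, where each window's standard
error comes from its spectral density at frequency zero (estimated by an
AIC-selected autoregressive fit, the diagnostic's canonical estimator).
Under convergence z is asymptotically standard normal; estimates with
two-sided p below 0.01 are flagged as unlikely to have converged.

A convergence report additionally selects a small plot sample of areas —
those with the smallest totals plus a seeded random selection, 5% of areas
by default — and emits trace, density and autocorrelation data tables for
external rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_toeplitz

from .config import GEWEKE_ALPHA, GEWEKE_FIRST_N, GEWEKE_LAST_N, PLOT_SAMPLE_FRACTION

__all__ = [
    "geweke_z",
    "autocorrelation",
    "convergence_report",
    "spectrum0_ar",
    "mcse",
    "GewekeResult",
    "ConvergenceReport",
]


def mcse(chain: np.ndarray, max_lag: int | None = None) -> float:
    """Monte-Carlo standard error of the chain mean via the integrated
    autocorrelation time (initial positive sequence truncation)."""
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 10:
        raise ValueError("chain too short")
    if chain.std() == 0:
        return 0.0
    if max_lag is None:
        max_lag = min(n // 4, 1000)
    acf = autocorrelation(chain, max_lag)[1:]
    cut = int(np.argmax(acf < 0)) if np.any(acf < 0) else len(acf)
    tau = 1.0 + 2.0 * float(acf[:cut].sum())
    return float(chain.std() * math.sqrt(max(tau, 1.0) / n))


@dataclass(frozen=True)
class GewekeResult:
    z: float
    p: float


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    return np.array([xc[: n - k] @ xc[k:] / n for k in range(max_lag + 1)])


def spectrum0_ar(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density at frequency zero via a Yule-Walker AR fit with the
    order chosen by AIC (including order 0)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("window too short for a spectral estimate")
    if max_order is None:
        max_order = min(int(10 * math.log10(n)), n // 4, 30)
    gamma = _autocovariances(x, max_order)
    if gamma[0] <= 0:
        return 0.0
    best_aic = n * math.log(gamma[0]) + 2  # order 0 (+1 variance parameter)
    best_s0 = gamma[0]
    for p in range(1, max_order + 1):
        try:
            phi = solve_toeplitz(gamma[:p], gamma[1 : p + 1])
        except np.linalg.LinAlgError:
            break
        sigma2 = gamma[0] - phi @ gamma[1 : p + 1]
        if sigma2 <= 0:
            continue
        aic = n * math.log(sigma2) + 2 * (p + 1)
        if aic < best_aic:
            denom = 1.0 - phi.sum()
            if abs(denom) < 1e-10:
                continue
            best_aic = aic
            best_s0 = sigma2 / denom**2
    return float(best_s0)


def geweke_z(
    chain: np.ndarray,
    first_n: int = GEWEKE_FIRST_N,
    last_n: int = GEWEKE_LAST_N,
) -> GewekeResult:
    """Geweke convergence statistic for one scalar chain of kept draws.

    z = (mean of first ``first_n`` - mean of last ``last_n``) divided by the
    asymptotic standard error of the difference; p is the two-sided normal
    tail probability.  A constant chain gives z = 0, p = 1.
    """
    chain = np.asarray(chain, dtype=float)
    if len(chain) < first_n + last_n:
        raise ValueError(
            f"chain of length {len(chain)} shorter than first_n + last_n "
            f"({first_n} + {last_n})"
        )
    a = chain[:first_n]
    b = chain[-last_n:]
    if np.ptp(chain) == 0:
        return GewekeResult(0.0, 1.0)
    var = spectrum0_ar(a) / first_n + spectrum0_ar(b) / last_n
    if var <= 0:
        return GewekeResult(0.0, 1.0)
    z = float((a.mean() - b.mean()) / math.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return GewekeResult(z, p)


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag (lag 0 is exactly 1)."""
    chain = np.asarray(chain, dtype=float)
    if max_lag >= len(chain):
        raise ValueError("max_lag must be smaller than the chain length")
    gamma = _autocovariances(chain, max_lag)
    if gamma[0] == 0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    return gamma / gamma[0]


@dataclass(frozen=True)
class ConvergenceReport:
    area_ids: tuple[str, ...]
    z: np.ndarray
    p: np.ndarray
    flagged: np.ndarray
    fraction_flagged: float
    plot_sample: tuple[str, ...]
    plot_data: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": list(self.area_ids),
                "z": self.z,
                "p": self.p,
                "flagged": self.flagged,
            }
        )


def convergence_report(
    chains: np.ndarray,
    area_ids,
    counts=None,
    alpha: float = GEWEKE_ALPHA,
    plot_fraction: float = PLOT_SAMPLE_FRACTION,
    first_n: int = GEWEKE_FIRST_N,
    last_n: int = GEWEKE_LAST_N,
    seed: int = 0,
    acf_max_lag: int = 50,
) -> ConvergenceReport:
    """Geweke screening of every area-level chain plus plot-sample tables.

    ``chains`` has shape (draws, areas).  The plot sample (``plot_fraction``
    of areas, rounded up) is composed of the areas with the smallest
    ``counts`` (areas of concern due to small numbers; half the sample) and a
    seeded random selection of the remainder.  For each sampled area trace,
    kernel-density and autocorrelation data tables are emitted.
    """
    chains = np.asarray(chains, dtype=float)
    n_areas = chains.shape[1]
    if len(area_ids) != n_areas:
        raise ValueError("area_ids must match the chain count")
    res = [geweke_z(chains[:, i], first_n, last_n) for i in range(n_areas)]
    z = np.array([r.z for r in res])
    p = np.array([r.p for r in res])
    flagged = p < alpha

    n_plot = min(n_areas, math.ceil(plot_fraction * n_areas))
    rng = np.random.default_rng(seed)
    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        n_small = n_plot // 2
        small = list(np.argsort(counts, kind="stable")[:n_small])
    else:
        small = []
    pool = np.setdiff1d(np.arange(n_areas), small)
    extra = rng.choice(pool, size=n_plot - len(small), replace=False)
    sample_idx = sorted(set(small) | set(int(i) for i in extra))
    plot_data = {}
    for i in sample_idx:
        x = chains[:, i]
        acf = autocorrelation(x, min(acf_max_lag, len(x) - 1))
        if np.ptp(x) > 0:
            kde = stats.gaussian_kde(x)
            grid = np.linspace(x.min(), x.max(), 128)
            dens = kde(grid)
        else:
            grid = np.array([x[0]])
            dens = np.array([1.0])
        plot_data[area_ids[i]] = {
            "trace": pd.DataFrame({"iteration": np.arange(len(x)), "value": x}),
            "density": pd.DataFrame({"value": grid, "density": dens}),
            "acf": pd.DataFrame({"lag": np.arange(len(acf)), "acf": acf}),
        }
    return ConvergenceReport(
        area_ids=tuple(area_ids),
        z=z,
        p=p,
        flagged=flagged,
        fraction_flagged=float(flagged.mean()),
        plot_sample=tuple(area_ids[i] for i in sample_idx),
        plot_data=plot_data,
    )
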