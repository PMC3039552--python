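"""Synthetic registry-like data.

Generates every input the analysis pipeline consumes — a lattice geography
with detached island areas, populations over 18 five-year age groups by sex
and year, a Gompertz-like population life table, Poisson incidence counts
driven by log-relative-risks alpha + u_i + v_i (u an intrinsic CAR field,
v Gaussian noise), and individual survival records whose hazard is the
background life-table mortality plus a piecewise-constant excess hazard
exp(alpha_j + beta_k + u_i + v_i) varying by follow-up year, broad age group
and area — so the smoothing models, diagnostics and clustering test are
exercisable without any external data.  Every generator is a pure function
of its seed and parameters.

The exact intrinsic CAR field is improper, so its "marginal scale" is
defined empirically: the field is drawn by Gibbs sweeps on the CAR full
conditionals, centred, and rescaled to the requested empirical standard
deviation.  Survival event times are piecewise exponential at yearly
resolution, matching the fitting model's assumption exactly so that
parameter-recovery tests probe the sampler rather than model error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .config import DEFAULT_BROAD_AGE_GROUPS
from .containers import IncidenceDataset
from .geography import AreaGraph, build_queen_adjacency
from .prep import DAYS_PER_YEAR, LifeTable

__all__ = [
    "AGE_GROUPS",
    "AGE_MIDPOINTS",
    "make_geography",
    "sample_icar",
    "simulate_populations_and_lifetable",
    "simulate_incidence",
    "simulate_survival_records",
    "SimulatedIncidence",
    "SimulatedSurvival",
]

# 18 five-year age groups, 0-4 ... 85+
AGE_GROUPS = tuple(
    [f"{5 * i}-{5 * i + 4}" for i in range(17)] + ["85+"]
)
AGE_LOWER = np.array([5 * i for i in range(18)], dtype=float)
AGE_MIDPOINTS = np.array([5 * i + 2.5 for i in range(17)] + [90.0])


def make_geography(
    n_rows: int, n_cols: int, n_islands: int = 0, seed: int = 0
) -> tuple[list[tuple[str, Polygon]], AreaGraph]:
    """Unit-square lattice plus detached island polygons.

    Islands sit strictly below the lattice, beyond any boundary contact with
    it or with each other, so they are isolates under queen contiguity until
    repaired.  Returns the polygons and the (pre-repair) queen graph.
    """
    if n_rows * n_cols + n_islands < 2:
        raise ValueError("need at least two areas")
    rng = np.random.default_rng(seed)
    polygons: list[tuple[str, Polygon]] = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            polygons.append(
                (f"a{k:04d}", Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)]))
            )
            k += 1
    for isl in range(n_islands):
        x0 = 2.0 * isl + rng.uniform(0, 0.5)
        y0 = -3.0 - rng.uniform(0, 0.5)
        polygons.append(
            (f"a{k:04d}", Polygon([(x0, y0), (x0 + 1, y0), (x0 + 1, y0 + 1), (x0, y0 + 1)]))
        )
        k += 1
    return polygons, build_queen_adjacency(polygons)


def sample_icar(
    graph: AreaGraph, sigma: float, rng: np.random.Generator, sweeps: int = 200
) -> np.ndarray:
    """Draw a centred intrinsic CAR field with empirical sd ``sigma`` by
    Gibbs sweeps on the CAR full conditionals (unit precision), then centring
    and rescaling.  Requires an isolate-free graph."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    n = graph.n_areas
    if sigma == 0:
        return np.zeros(n)
    if graph.isolates():
        raise ValueError("CAR field needs an isolate-free graph")
    deg = graph.degrees.astype(float)
    w = graph.adjacency_matrix()
    u = np.zeros(n)
    for _ in range(sweeps):
        for idx in graph.colour_classes():
            mean = np.asarray(w @ u)[idx] / deg[idx]
            u[idx] = mean + rng.standard_normal(len(idx)) / np.sqrt(deg[idx])
        u -= u.mean()
    sd = u.std()
    if sd > 0:
        u *= sigma / sd
    return u


def simulate_populations_and_lifetable(
    graph: AreaGraph,
    mean_pop: float = 8000.0,
    dispersion: float = 0.5,
    base_mortality: float = 3e-5,
    years: tuple[int, int] = (1998, 2007),
    extra_lifetable_years: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, LifeTable]:
    """Area populations over 18 age groups x 2 sexes x study years, and a
    matching life table.

    Area sizes are log-normal around ``mean_pop`` persons (sd of log sizes =
    ``dispersion``; zero dispersion gives identical areas); the age structure
    declines smoothly with age and is shared by all areas; sexes split
    evenly.  Life-table rates are Gompertz-like in age (doubling roughly
    every 8 years), slightly higher for males, constant over calendar years,
    and extend ``extra_lifetable_years`` beyond the study window so follow-up
    lookups stay in-domain.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_areas
    if dispersion == 0:
        sizes = np.full(n, mean_pop)
    else:
        sizes = mean_pop * np.exp(
            rng.normal(-dispersion**2 / 2, dispersion, size=n)
        )
    age_w = np.exp(-0.025 * AGE_MIDPOINTS)
    age_w /= age_w.sum()
    year_list = list(range(years[0], years[1] + 1))
    rows = []
    for i, aid in enumerate(graph.area_ids):
        for sex in ("female", "male"):
            for g, w_g in zip(AGE_GROUPS, age_w):
                py = sizes[i] * w_g * 0.5
                for yr in year_list:
                    rows.append((aid, sex, g, yr, py))
    populations = pd.DataFrame(
        rows, columns=["area_id", "sex", "age_group", "year", "person_years"]
    )
    lt_rows = []
    for sex, mult in (("female", 0.9), ("male", 1.3)):
        for lo, mid in zip(AGE_LOWER, AGE_MIDPOINTS):
            rate = base_mortality * mult * np.exp(0.085 * mid)
            for yr in range(years[0], years[1] + 1 + extra_lifetable_years):
                lt_rows.append((sex, lo, yr, rate))
    life_table = LifeTable(
        pd.DataFrame(lt_rows, columns=["sex", "age", "year", "rate"])
    )
    return populations, life_table


@dataclass(frozen=True)
class SimulatedIncidence:
    data: IncidenceDataset
    theta: np.ndarray
    u: np.ndarray
    v: np.ndarray


def simulate_incidence(
    graph: AreaGraph,
    alpha: float = 0.0,
    sigma_u: float = 0.3,
    sigma_v: float = 0.1,
    expected: np.ndarray | None = None,
    populations: pd.DataFrame | None = None,
    base_rates: np.ndarray | None = None,
    seed: int = 0,
) -> SimulatedIncidence:
    """Poisson counts y_i ~ Poisson(e_i exp(alpha + u_i + v_i)) with the
    planted field returned for recovery tests.

    Expected counts come either directly from ``expected`` or from an
    age-specific rate schedule applied to a population table (per-area
    person-years by age group, pooled over sexes and years).
    """
    rng = np.random.default_rng(seed)
    n = graph.n_areas
    if expected is None:
        if populations is None:
            raise ValueError("provide expected counts or a population table")
        if base_rates is None:
            # smooth age gradient typical of adult solid cancers
            base_rates = 1e-5 * np.exp(0.055 * AGE_MIDPOINTS)
        base_rates = np.asarray(base_rates, dtype=float)
        py = populations.pivot_table(
            index="area_id", columns="age_group", values="person_years",
            aggfunc="sum",
        ).reindex(index=list(graph.area_ids), columns=list(AGE_GROUPS))
        expected = (py.to_numpy() * base_rates[None, :]).sum(axis=1)
    expected = np.asarray(expected, dtype=float)
    if expected.shape != (n,):
        raise ValueError("expected counts must align with the graph")
    u = sample_icar(graph, sigma_u, rng)
    v = rng.normal(0.0, sigma_v, size=n) if sigma_v > 0 else np.zeros(n)
    theta = np.exp(alpha + u + v)
    y = rng.poisson(expected * theta)
    return SimulatedIncidence(
        IncidenceDataset(graph.area_ids, y, expected), theta, u, v
    )


@dataclass(frozen=True)
class SimulatedSurvival:
    records: pd.DataFrame
    log_rer: np.ndarray
    u: np.ndarray
    v: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray


def simulate_survival_records(
    graph: AreaGraph,
    alpha_j,
    beta_k,
    populations: pd.DataFrame,
    life_table: LifeTable,
    n_cases: int,
    window: tuple,
    sigma_u: float = 0.0,
    sigma_v: float = 0.0,
    area_log_rer: np.ndarray | None = None,
    broad_age_groups=DEFAULT_BROAD_AGE_GROUPS,
    frac_dco: float = 0.01,
    frac_autopsy: float = 0.005,
    frac_age90: float = 0.02,
    seed: int = 0,
) -> SimulatedSurvival:
    """Individual survival records under background + piecewise-constant
    excess hazard.

    In follow-up year j a case's total hazard is the life-table rate at its
    attained age, sex and calendar year plus exp(alpha_j + beta_k + u_i +
    v_i); event times are drawn piecewise-exponentially across year
    boundaries and survivors at the window end are censored.  ``area_log_rer``
    overrides the sampled u + v field (for planted-signal studies).  Small
    fractions of records are marked death-certificate-only / autopsy-only or
    given age >= 90 to exercise the exclusion rules.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_areas
    alpha_j = np.asarray(alpha_j, dtype=float)
    beta_k = np.asarray(beta_k, dtype=float)
    n_j = len(alpha_j)
    bounds = np.asarray(broad_age_groups, dtype=float)
    if len(beta_k) != len(bounds):
        raise ValueError("beta_k must match the broad age groups")
    if beta_k[0] != 0:
        raise ValueError("beta_k[0] is the reference and must be 0")
    if area_log_rer is not None:
        log_rer = np.asarray(area_log_rer, dtype=float)
        if log_rer.shape != (n,):
            raise ValueError("area_log_rer must align with the graph")
        u = log_rer.copy()
        v = np.zeros(n)
    else:
        u = sample_icar(graph, sigma_u, rng)
        v = rng.normal(0.0, sigma_v, size=n) if sigma_v > 0 else np.zeros(n)
        log_rer = u + v

    win_start = pd.Timestamp(window[0])
    win_end = pd.Timestamp(window[1])
    span_days = (win_end - win_start).days

    # areas weighted by population, ages by an adult-skewed schedule
    py_area = (
        populations.groupby("area_id")["person_years"].sum()
        .reindex(list(graph.area_ids))
    )
    p_area = (py_area / py_area.sum()).to_numpy()
    py_age = (
        populations.groupby("age_group")["person_years"].sum()
        .reindex(list(AGE_GROUPS)).to_numpy()
    )
    age_w = py_age * np.exp(0.05 * AGE_MIDPOINTS)
    age_w[AGE_LOWER < 30] = 0.0
    age_w /= age_w.sum()

    area_idx = rng.choice(n, size=n_cases, p=p_area)
    sex = np.where(rng.uniform(size=n_cases) < 0.5, "female", "male")
    band = rng.choice(len(AGE_GROUPS), size=n_cases, p=age_w)
    age0 = AGE_LOWER[band] + rng.uniform(0, 5, size=n_cases)
    age0 = np.minimum(age0, 89.0)
    n90 = int(round(frac_age90 * n_cases))
    if n90:
        age0[rng.choice(n_cases, size=n90, replace=False)] = rng.uniform(
            90, 99, size=n90
        )
    diag_offset = rng.uniform(0, span_days, size=n_cases)
    diag = win_start + pd.to_timedelta(np.floor(diag_offset), unit="D")
    k_idx = np.searchsorted(bounds, age0, side="right") - 1
    k_idx = np.clip(k_idx, 0, len(bounds) - 1)

    excess_area = log_rer[area_idx]
    t_death = np.full(n_cases, np.inf)  # years since diagnosis
    alive = np.ones(n_cases, dtype=bool)
    for j in range(1, n_j + 1):
        mid_date = diag + pd.to_timedelta((j - 0.5) * DAYS_PER_YEAR, unit="D")
        bg = life_table.rate(sex, age0 + (j - 0.5), mid_date.year.to_numpy())
        hazard = bg + np.exp(alpha_j[j - 1] + beta_k[k_idx] + excess_area)
        t = rng.exponential(1.0, size=n_cases) / hazard
        dies = alive & (t < 1.0)
        t_death[dies] = (j - 1) + t[dies]
        alive &= ~dies
    t_capped = np.where(np.isfinite(t_death), t_death, float(n_j) + 1.0)
    death_date = (diag + pd.to_timedelta(t_capped * DAYS_PER_YEAR, unit="D")).to_numpy()
    died = (~alive) & (death_date <= np.datetime64(win_end))
    followup_end = (diag + pd.to_timedelta(n_j * DAYS_PER_YEAR, unit="D")).to_numpy()
    censor_date = np.minimum(followup_end, np.datetime64(win_end))
    exit_date = np.where(died, death_date, censor_date)

    dco = rng.uniform(size=n_cases) < frac_dco
    autopsy = (~dco) & (rng.uniform(size=n_cases) < frac_autopsy)
    records = pd.DataFrame(
        {
            "area_id": [graph.area_ids[i] for i in area_idx],
            "sex": sex,
            "age_years": age0,
            "diag_date": pd.DatetimeIndex(diag),
            "exit_date": pd.DatetimeIndex(exit_date),
            "died": died,
            "dco": dco,
            "autopsy": autopsy,
        }
    )
    return SimulatedSurvival(records, log_rer, u, v, alpha_j.copy(), beta_k.copy())
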