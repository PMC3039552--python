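"""Map classification, stratum aggregation and export products.

Smoothed ratios are classified into five symmetric map classes cut at 10%
and 30% above the regional average and the inverses below it; the central
class is closed, so 1.1 itself is "average" and 1.3 itself is "above".

Posterior draws are aggregated to area strata (socioeconomic quintile,
rurality) by computing, per kept iteration, the modelled observed value of
every area (theta_i x e_i for incidence; adjusted deaths for survival),
summing within the stratum, dividing by the summed expected values, and
summarising the resulting ratio chain by its median and 2.5/97.5
percentiles.  All percentile operations use linear interpolation between
order statistics (type 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MAP_CUTOFFS
from .containers import PosteriorDraws, SmoothedEstimates
from .geography import write_geojson_polygons

__all__ = [
    "MAP_CATEGORIES",
    "categorize_for_map",
    "StratumAssignment",
    "make_quintiles",
    "group_estimates",
    "export_products",
]

MAP_CATEGORIES = ("well below", "below", "average", "above", "well above")


def categorize_for_map(estimate: float) -> str:
    """Five-class map category of a positive ratio estimate.

    Classes: (0, 1/1.3), [1/1.3, 1/1.1), [1/1.1, 1.1], (1.1, 1.3],
    (1.3, inf) labelled well below / below / average / above / well above.
    """
    x = float(estimate)
    if not x > 0:
        raise ValueError("map classification needs a positive estimate")
    lo_wide, lo, hi, hi_wide = MAP_CUTOFFS
    if x < lo_wide:
        return MAP_CATEGORIES[0]
    if x < lo:
        return MAP_CATEGORIES[1]
    if x <= hi:
        return MAP_CATEGORIES[2]
    if x <= hi_wide:
        return MAP_CATEGORIES[3]
    return MAP_CATEGORIES[4]


RURALITY_LEVELS = ("major city", "inner regional", "outer regional", "remote")


@dataclass(frozen=True)
class StratumAssignment:
    """Per-area stratum labels: socioeconomic quintile (1 = most
    disadvantaged) and rurality category (remote and very remote merged
    upstream)."""

    area_ids: tuple[str, ...]
    ses_quintile: np.ndarray
    rurality: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        q = np.asarray(self.ses_quintile, dtype=int)
        if q.shape != (n,) or len(self.rurality) != n:
            raise ValueError("assignment must cover every area exactly once")
        if np.any((q < 1) | (q > 5)):
            raise ValueError("quintiles must lie in 1..5")
        object.__setattr__(self, "ses_quintile", q)

    def groups(self, by: str) -> dict[str, np.ndarray]:
        """Stratum label -> member area indices."""
        if by == "ses":
            labels = [f"Q{q}" for q in self.ses_quintile]
        elif by == "rurality":
            labels = list(self.rurality)
        else:
            raise ValueError("by must be 'ses' or 'rurality'")
        out: dict[str, list[int]] = {}
        for i, lab in enumerate(labels):
            out.setdefault(lab, []).append(i)
        return {k: np.array(v, dtype=int) for k, v in sorted(out.items())}


def make_quintiles(scores: np.ndarray) -> np.ndarray:
    """Rank areas by a disadvantage score (most disadvantaged first) and
    split into five near-equal groups, 1..5."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    return (rank * 5) // n + 1


def _per_draw_observed(
    draws: PosteriorDraws, expected, cells=None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-iteration modelled observed values (T, n) and the fixed per-area
    expected totals (n,)."""
    if draws.kind == "incidence":
        e = np.asarray(expected, dtype=float)
        return draws.theta() * e[None, :], e
    from .survival import point_estimates

    if cells is None:
        raise ValueError("survival aggregation needs the cell table")
    n = cells.n_areas
    a = draws.params["alpha"]
    b = draws.params["beta"]
    rer = draws.rer()
    base = cells.y[None, :] * np.exp(
        a[:, cells.interval - 1] + b[:, cells.age_idx]
    )
    from scipy import sparse

    m = sparse.csr_matrix(
        (np.ones(cells.n_cells), (np.arange(cells.n_cells), cells.area_idx)),
        shape=(cells.n_cells, n),
    )
    ds = np.bincount(cells.area_idx, weights=cells.dstar, minlength=n)
    obs = (base * rer[:, cells.area_idx]) @ m + ds[None, :]
    # expected totals at the posterior-median coefficients with RER = 1
    from .survival import adjusted_deaths

    _, e_fixed = adjusted_deaths(point_estimates(draws), cells)
    return np.asarray(obs), e_fixed


def group_estimates(
    draws: PosteriorDraws,
    assignment: StratumAssignment,
    by: str = "ses",
    expected=None,
    cells=None,
) -> pd.DataFrame:
    """Stratum-level ratio estimates from the posterior draws.

    Per iteration t the stratum ratio is sum_{i in stratum} O_i^(t) divided
    by the stratum's summed expected values; the table reports the median
    and the 2.5/97.5 percentiles of that chain per stratum.
    """
    if tuple(assignment.area_ids) != tuple(draws.area_ids):
        raise ValueError("assignment and draws must cover the same areas")
    obs, e = _per_draw_observed(draws, expected, cells)
    rows = []
    for label, idx in assignment.groups(by).items():
        if len(idx) == 0:
            raise ValueError(f"empty stratum {label!r}")
        denom = e[idx].sum()
        if denom <= 0:
            raise ValueError(f"stratum {label!r} has no expected events")
        ratio = obs[:, idx].sum(axis=1) / denom
        med = float(np.median(ratio))
        lo, hi = np.percentile(ratio, [2.5, 97.5])
        rows.append(
            {
                "stratum": label,
                "n_areas": len(idx),
                "median": med,
                "lo95": float(lo),
                "hi95": float(hi),
            }
        )
    return pd.DataFrame(rows)


def export_products(
    polygons: Sequence[tuple[str, object]],
    estimates: SmoothedEstimates,
    assignment: StratumAssignment | None = None,
) -> dict[str, object]:
    """Standard atlas export products.

    Returns a dict with: ``geojson`` — a choropleth FeatureCollection whose
    features carry median/lo95/hi95/category properties; ``caterpillar`` —
    areas ranked by posterior median with their intervals; and, when an
    assignment is given, ``boxplot_ses`` / ``boxplot_rurality`` — five-number
    summaries (min, q1, median, q3, max) of the area medians per stratum.
    """
    poly_ids = [aid for aid, _ in polygons]
    if set(poly_ids) != set(estimates.area_ids):
        raise ValueError("polygon ids do not match estimate ids")
    ix = {aid: i for i, aid in enumerate(estimates.area_ids)}
    props = {
        aid: {
            "median": float(estimates.median[ix[aid]]),
            "lo95": float(estimates.lo95[ix[aid]]),
            "hi95": float(estimates.hi95[ix[aid]]),
            "category": estimates.category[ix[aid]],
        }
        for aid in poly_ids
    }
    geojson = write_geojson_polygons(polygons, props)
    order = np.argsort(estimates.median, kind="stable")
    caterpillar = pd.DataFrame(
        {
            "rank": np.arange(1, estimates.n_areas + 1),
            "area_id": [estimates.area_ids[i] for i in order],
            "median": estimates.median[order],
            "lo95": estimates.lo95[order],
            "hi95": estimates.hi95[order],
        }
    )
    out: dict[str, object] = {"geojson": geojson, "caterpillar": caterpillar}
    if assignment is not None:
        if tuple(assignment.area_ids) != tuple(estimates.area_ids):
            raise ValueError("assignment and estimates must cover the same areas")
        for by in ("ses", "rurality"):
            rows = []
            for label, idx in assignment.groups(by).items():
                med = estimates.median[idx]
                q1, q2, q3 = np.percentile(med, [25, 50, 75])
                rows.append(
                    {
                        "stratum": label,
                        "min": float(med.min()),
                        "q1": float(q1),
                        "median": float(q2),
                        "q3": float(q3),
                        "max": float(med.max()),
                    }
                )
            out[f"boxplot_{by}"] = pd.DataFrame(rows)
    return out
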