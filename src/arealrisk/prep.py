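"""Registry-style data preparation.

Turns raw inputs — case counts, population tables, individual survival
records and a population life table — into the structures the smoothing
models consume:

- expected incidence counts by indirect standardisation (the pooled dataset
  is its own reference, so expected counts sum to observed counts per sex);
- survival-record exclusions (age at diagnosis >= 90, death-certificate-only
  or autopsy-only registrations, zero-or-negative survival time, no at-risk
  time inside the study window);
- collapsed person-time cells (broad age group x follow-up year x area) with
  exact day-level person-years, observed deaths, and expected background
  deaths from the life table.

Dates are handled at day precision; person-years are days / 365.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_BROAD_AGE_GROUPS
from .containers import IncidenceDataset

__all__ = [
    "LifeTable",
    "SurvivalCellTable",
    "expected_incidence_counts",
    "apply_survival_exclusions",
    "collapse_person_time",
    "broad_age_labels",
]

DAYS_PER_YEAR = 365.25

RECORD_COLUMNS = (
    "area_id", "sex", "age_years", "diag_date", "exit_date",
    "died", "dco", "autopsy",
)


class LifeTable:
    """All-cause mortality rates (per person-year) by age, sex and calendar
    year.

    ``frame`` needs columns (sex, age, year, rate) where ``age`` is the lower
    bound of a single-year or 5-year band; the top band is open-ended.
    Lookups outside the tabulated years, or below the lowest age band, are
    rejected.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "age", "year", "rate"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        if (frame["rate"] < 0).any():
            raise ValueError("life-table rates must be non-negative")
        self.frame = frame.copy()
        self.ages = np.sort(frame["age"].unique()).astype(float)
        self.years = np.sort(frame["year"].unique()).astype(int)
        self.sexes = tuple(sorted(frame["sex"].unique()))
        if not np.array_equal(self.years, np.arange(self.years[0], self.years[-1] + 1)):
            raise ValueError("life-table years must be contiguous")
        self._rates: dict[str, np.ndarray] = {}
        for sex in self.sexes:
            sub = frame[frame["sex"] == sex]
            piv = sub.pivot_table(index="age", columns="year", values="rate")
            piv = piv.reindex(index=self.ages, columns=self.years)
            if piv.isna().any().any():
                raise ValueError(f"life table incomplete for sex {sex!r}")
            self._rates[sex] = piv.to_numpy(dtype=float)

    def rate(self, sex, age, year) -> np.ndarray:
        """Vectorised lookup; ``age`` may be fractional (band lookup)."""
        sex = np.asarray(sex)
        age = np.asarray(age, dtype=float)
        year = np.asarray(year, dtype=int)
        if np.any(age < self.ages[0]):
            raise ValueError("attained age below life-table domain")
        if np.any((year < self.years[0]) | (year > self.years[-1])):
            raise ValueError("calendar year outside life-table domain")
        band = np.searchsorted(self.ages, age, side="right") - 1
        ycol = year - self.years[0]
        out = np.empty(age.shape, dtype=float)
        for s in self.sexes:
            mask = sex == s
            out[mask] = self._rates[s][band[mask], ycol[mask]]
        unknown = ~np.isin(sex, self.sexes)
        if np.any(unknown):
            raise ValueError(f"unknown sex value(s) {set(np.unique(sex[unknown]))}")
        return out


def expected_incidence_counts(
    cases: pd.DataFrame,
    populations: pd.DataFrame,
    area_ids: Sequence[str] | None = None,
) -> dict[str, IncidenceDataset]:
    """Indirectly standardised expected counts, separately per sex.

    ``cases``: (area_id, sex, age_group, year, n); ``populations``:
    (area_id, sex, age_group, year, person_years); both aggregated over the
    study years.  The pooled dataset supplies the reference age-specific
    rates, so sum(e_i) = sum(y_i) within each sex.  An area recording cases
    but no population is rejected.
    """
    for df, cols in ((cases, {"area_id", "sex", "age_group", "n"}),
                     (populations, {"area_id", "sex", "age_group", "person_years"})):
        if not cols.issubset(df.columns):
            raise ValueError(f"missing columns; need {sorted(cols)}")
    if area_ids is None:
        area_ids = sorted(populations["area_id"].unique())
    area_ids = list(area_ids)
    out: dict[str, IncidenceDataset] = {}
    for sex in sorted(populations["sex"].unique()):
        pop_s = populations[populations["sex"] == sex]
        cas_s = cases[cases["sex"] == sex]
        py = pop_s.groupby(["area_id", "age_group"])["person_years"].sum()
        cs = cas_s.groupby(["area_id", "age_group"])["n"].sum()
        # reference rates pooled over the whole region
        py_age = pop_s.groupby("age_group")["person_years"].sum()
        cs_age = cas_s.groupby("age_group")["n"].sum().reindex(py_age.index, fill_value=0)
        if (cs_age[py_age <= 0] > 0).any():
            raise ValueError("cases recorded in an age group with zero person-years")
        rate = np.where(py_age > 0, cs_age / py_age.replace(0, np.nan), 0.0)
        rate = pd.Series(rate, index=py_age.index).fillna(0.0)
        y = np.zeros(len(area_ids))
        e = np.zeros(len(area_ids))
        py_area = py.groupby("area_id").sum()
        cs_area = cs.groupby("area_id").sum()
        for bad in set(cs_area.index) - set(area_ids):
            raise ValueError(f"cases in unknown area {bad!r}")
        for i, aid in enumerate(area_ids):
            y[i] = cs_area.get(aid, 0)
            if y[i] > 0 and py_area.get(aid, 0.0) <= 0:
                raise ValueError(
                    f"area {aid!r} has cases but zero population"
                )
            if aid in py.index.get_level_values(0):
                py_i = py.loc[aid]
                e[i] = float((rate.reindex(py_i.index).fillna(0.0) * py_i).sum())
        out[sex] = IncidenceDataset(tuple(area_ids), y, e)
    return out


def apply_survival_exclusions(
    records: pd.DataFrame,
    window: tuple,
    max_followup_years: int = 5,
    max_age: float = 90.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the survival-analysis exclusion rules.

    Drops, in order of precedence: age at diagnosis >= ``max_age``;
    death-certificate-only registrations; autopsy-only registrations;
    survival time <= 0 days; and records contributing no at-risk time inside
    ``window`` (start, end) within ``max_followup_years`` of diagnosis.
    Returns the retained records and a tally of exclusions by reason.
    A record whose exit precedes diagnosis without a death flag is treated as
    corrupt and rejected outright.
    """
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    rec = records.copy()
    diag = pd.to_datetime(rec["diag_date"])
    exit_ = pd.to_datetime(rec["exit_date"])
    win_start, win_end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    surv_days = (exit_ - diag).dt.days
    corrupt = (surv_days < 0) & ~rec["died"].astype(bool)
    if corrupt.any():
        bad = rec.index[corrupt].tolist()
        raise ValueError(f"corrupt record(s) {bad}: exit precedes diagnosis")
    reason = pd.Series("", index=rec.index, dtype=object)
    reason[(reason == "") & (rec["age_years"] >= max_age)] = "age"
    reason[(reason == "") & rec["dco"].astype(bool)] = "dco"
    reason[(reason == "") & rec["autopsy"].astype(bool)] = "autopsy"
    reason[(reason == "") & (surv_days <= 0)] = "zero_survival"
    cap = diag + pd.to_timedelta(max_followup_years * DAYS_PER_YEAR, unit="D")
    in_window = (diag <= win_end) & (exit_ > win_start) & (cap > win_start)
    reason[(reason == "") & ~in_window] = "outside_window"
    tally = reason[reason != ""].value_counts().to_dict()
    tally["included"] = int((reason == "").sum())
    return rec[reason == ""].copy(), tally


def broad_age_labels(bounds: Sequence[float]) -> tuple[str, ...]:
    """Human-readable labels for broad age-group lower bounds."""
    labels = []
    for i, lo in enumerate(bounds):
        if i + 1 < len(bounds):
            labels.append(f"{int(lo)}-{int(bounds[i + 1]) - 1}")
        else:
            labels.append(f"{int(lo)}+")
    return tuple(labels)


@dataclass(frozen=True)
class SurvivalCellTable:
    """Collapsed survival cells indexed (k: broad age group, j: follow-up
    interval 1..n_intervals, i: area) with person-years ``y``, observed
    deaths ``d`` and expected background deaths ``dstar``."""

    area_ids: tuple[str, ...]
    age_groups: tuple[str, ...]
    n_intervals: int
    age_idx: np.ndarray
    interval: np.ndarray
    area_idx: np.ndarray
    y: np.ndarray
    d: np.ndarray
    dstar: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.y)
        for name in ("age_idx", "interval", "area_idx", "d"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (m,):
                raise ValueError("cell arrays must share length")
            object.__setattr__(self, name, arr)
        for name in ("y", "dstar"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if np.any(self.y < 0) or np.any(self.dstar < 0) or np.any(self.d < 0):
            raise ValueError("person-time, deaths and expected deaths must be >= 0")
        if np.any((self.interval < 1) | (self.interval > self.n_intervals)):
            raise ValueError("interval index out of range")
        if np.any((self.age_idx < 0) | (self.age_idx >= len(self.age_groups))):
            raise ValueError("age-group index out of range")
        if np.any((self.area_idx < 0) | (self.area_idx >= len(self.area_ids))):
            raise ValueError("area index out of range")

    @property
    def n_cells(self) -> int:
        return len(self.y)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": [self.area_ids[i] for i in self.area_idx],
                "age_group": [self.age_groups[k] for k in self.age_idx],
                "interval": self.interval,
                "person_years": self.y,
                "deaths": self.d,
                "expected_deaths": self.dstar,
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        area_ids: Sequence[str] | None = None,
        age_groups: Sequence[str] | None = None,
        n_intervals: int | None = None,
    ) -> "SurvivalCellTable":
        if area_ids is None:
            area_ids = sorted(frame["area_id"].unique())
        if age_groups is None:
            age_groups = sorted(frame["age_group"].unique())
        if n_intervals is None:
            n_intervals = int(frame["interval"].max())
        a_ix = {a: i for i, a in enumerate(area_ids)}
        k_ix = {k: i for i, k in enumerate(age_groups)}
        return cls(
            tuple(area_ids),
            tuple(age_groups),
            n_intervals,
            frame["age_group"].map(k_ix).to_numpy(),
            frame["interval"].to_numpy(),
            frame["area_id"].map(a_ix).to_numpy(),
            frame["person_years"].to_numpy(dtype=float),
            frame["deaths"].to_numpy(dtype=int),
            frame["expected_deaths"].to_numpy(dtype=float),
        )


def collapse_person_time(
    records: pd.DataFrame,
    life_table: LifeTable,
    window: tuple,
    broad_age_groups: Sequence[float] = DEFAULT_BROAD_AGE_GROUPS,
    max_followup_years: int = 5,
    area_ids: Sequence[str] | None = None,
) -> SurvivalCellTable:
    """Split each record's at-risk time into follow-up-year cells.

    Follow-up is cut exactly at annual anniversaries of diagnosis and at the
    window boundaries; person-time is day-level exact.  Expected background
    deaths accumulate segment person-time times the life-table rate at the
    record's attained age, sex and calendar year at the segment midpoint.
    Cells with no person-time are dropped.
    """
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    if area_ids is None:
        area_ids = sorted(records["area_id"].unique())
    area_ids = list(area_ids)
    a_ix = {a: i for i, a in enumerate(area_ids)}
    unknown = set(records["area_id"]) - set(area_ids)
    if unknown:
        raise ValueError(f"records reference unknown area(s) {sorted(unknown)}")

    bounds = np.asarray(broad_age_groups, dtype=float)
    labels = broad_age_labels(bounds)
    n_rec = len(records)
    epoch = pd.Timestamp("1970-01-01")
    diag_d = (pd.to_datetime(records["diag_date"]) - epoch).dt.total_seconds().to_numpy() / 86400.0
    exit_d = (pd.to_datetime(records["exit_date"]) - epoch).dt.total_seconds().to_numpy() / 86400.0
    ws = (pd.Timestamp(window[0]) - epoch).total_seconds() / 86400.0
    we = (pd.Timestamp(window[1]) - epoch).total_seconds() / 86400.0
    age0 = records["age_years"].to_numpy(dtype=float)
    sex = records["sex"].to_numpy()
    died = records["died"].to_numpy(dtype=bool)
    area = records["area_id"].map(a_ix).to_numpy()

    k_idx = np.searchsorted(bounds, age0, side="right") - 1
    if np.any(k_idx < 0):
        bad = records.index[k_idx < 0].tolist()
        raise ValueError(f"record(s) {bad} below the first broad age group")

    cap_d = diag_d + max_followup_years * DAYS_PER_YEAR
    entry = np.maximum(diag_d, ws)
    exit_eff = np.minimum.reduce([exit_d, np.full(n_rec, we), cap_d])
    died_eff = died & (exit_d <= we + 1e-9) & (exit_d <= cap_d + 1e-9)
    t_death = exit_eff - diag_d
    j_death = np.clip(np.ceil(t_death / DAYS_PER_YEAR), 1, max_followup_years).astype(int)

    n_j = max_followup_years
    n_cells = len(labels) * n_j * len(area_ids)
    y_acc = np.zeros(n_cells)
    d_acc = np.zeros(n_cells, dtype=int)
    ds_acc = np.zeros(n_cells)

    def cell_of(k, j, i):
        return (k * n_j + (j - 1)) * len(area_ids) + i

    for j in range(1, n_j + 1):
        seg_a = np.maximum(diag_d + (j - 1) * DAYS_PER_YEAR, entry)
        seg_b = np.minimum(diag_d + j * DAYS_PER_YEAR, exit_eff)
        pt_days = np.maximum(seg_b - seg_a, 0.0)
        active = pt_days > 0
        if not np.any(active):
            continue
        mid = (seg_a + seg_b) / 2.0
        attained_age = age0[active] + (mid[active] - diag_d[active]) / DAYS_PER_YEAR
        mid_year = (
            pd.to_datetime(mid[active], unit="D", origin="unix")
            .year.to_numpy()
        )
        try:
            rates = life_table.rate(sex[active], attained_age, mid_year)
        except ValueError as err:
            bad = records.index[active].tolist()
            raise ValueError(
                f"life-table lookup failed for record(s) among {bad[:5]}: {err}"
            ) from err
        cells = cell_of(k_idx[active], j, area[active])
        pt_years = pt_days[active] / DAYS_PER_YEAR
        np.add.at(y_acc, cells, pt_years)
        np.add.at(ds_acc, cells, pt_years * rates)
        death_here = active & died_eff & (j_death == j)
        if np.any(death_here):
            np.add.at(
                d_acc, cell_of(k_idx[death_here], j, area[death_here]), 1
            )

    keep = y_acc > 0
    flat = np.nonzero(keep)[0]
    k_of = flat // (n_j * len(area_ids))
    j_of = (flat // len(area_ids)) % n_j + 1
    i_of = flat % len(area_ids)
    return SurvivalCellTable(
        tuple(area_ids),
        labels,
        n_j,
        k_of,
        j_of,
        i_of,
        y_acc[flat],
        d_acc[flat],
        ds_acc[flat],
    )
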