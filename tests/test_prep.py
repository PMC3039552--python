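import numpy as np
import pandas as pd
import pytest

from arealrisk.prep import (
    DAYS_PER_YEAR,
    LifeTable,
    apply_survival_exclusions,
    broad_age_labels,
    collapse_person_time,
    expected_incidence_counts,
)

WINDOW = ("1998-01-01", "2007-12-31")


def flat_life_table(rate: float, years=(1996, 2013)) -> LifeTable:
    rows = [
        (sex, age, yr, rate)
        for sex in ("female", "male")
        for age in range(0, 90, 5)
        for yr in range(years[0], years[1] + 1)
    ]
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "year", "rate"]))


def record(area="a", sex="female", age=60.0, diag="2000-01-01", exit="2003-01-01",
           died=False, dco=False, autopsy=False):
    return {
        "area_id": area, "sex": sex, "age_years": age, "diag_date": diag,
        "exit_date": exit, "died": died, "dco": dco, "autopsy": autopsy,
    }


class TestExpectedCounts:
    def make_tables(self, pops, cases):
        pop_rows = [
            (a, "female", g, 2000, p) for (a, g), p in pops.items()
        ]
        case_rows = [
            (a, "female", g, 2000, c) for (a, g), c in cases.items()
        ]
        return (
            pd.DataFrame(case_rows, columns=["area_id", "sex", "age_group", "year", "n"]),
            pd.DataFrame(pop_rows, columns=["area_id", "sex", "age_group", "year", "person_years"]),
        )

    def test_homogeneous_areas_give_unit_raw_ratios(self):
        pops = {(a, g): 100.0 for a in "abc" for g in ("0-4", "5-9")}
        cases = {(a, g): 4 for a in "abc" for g in ("0-4", "5-9")}
        cs, ps = self.make_tables(pops, cases)
        ds = expected_incidence_counts(cs, ps)["female"]
        assert np.allclose(ds.e, ds.y)
        assert np.allclose(ds.y / ds.e, 1.0)

    def test_single_area_absorbs_all_cases(self):
        pops = {("a", "0-4"): 500.0}
        cases = {("a", "0-4"): 17}
        cs, ps = self.make_tables(pops, cases)
        ds = expected_incidence_counts(cs, ps)["female"]
        assert ds.e[0] == pytest.approx(17.0)

    def test_three_area_hand_computation(self):
        # by-hand: rates young = 6/600 = 0.01, old = 9/300 = 0.03
        pops = {
            ("a", "young"): 100.0, ("a", "old"): 50.0,
            ("b", "young"): 200.0, ("b", "old"): 100.0,
            ("c", "young"): 300.0, ("c", "old"): 150.0,
        }
        cases = {
            ("a", "young"): 1, ("a", "old"): 2,
            ("b", "young"): 2, ("b", "old"): 3,
            ("c", "young"): 3, ("c", "old"): 4,
        }
        cs, ps = self.make_tables(pops, cases)
        ds = expected_incidence_counts(cs, ps)["female"]
        expected = {
            "a": 100 * 0.01 + 50 * 0.03,
            "b": 200 * 0.01 + 100 * 0.03,
            "c": 300 * 0.01 + 150 * 0.03,
        }
        for aid, e in zip(ds.area_ids, ds.e):
            assert e == pytest.approx(expected[aid])
        assert ds.e.sum() == pytest.approx(ds.y.sum())

    def test_cases_without_population_rejected(self):
        cs, ps = self.make_tables({("a", "0-4"): 10.0}, {("b", "0-4"): 1})
        with pytest.raises(ValueError):
            expected_incidence_counts(cs, ps, area_ids=["a", "b"])


class TestExclusions:
    def run(self, *records):
        return apply_survival_exclusions(pd.DataFrame(list(records)), WINDOW)

    def test_age_90_and_over_excluded(self):
        kept, tally = self.run(record(age=92.0))
        assert len(kept) == 0 and tally["age"] == 1

    def test_zero_survival_excluded(self):
        kept, tally = self.run(record(diag="2000-01-01", exit="2000-01-01", died=True))
        assert len(kept) == 0 and tally["zero_survival"] == 1

    def test_dco_and_autopsy_only_excluded(self):
        kept, tally = self.run(record(dco=True), record(autopsy=True))
        assert len(kept) == 0
        assert tally["dco"] == 1 and tally["autopsy"] == 1

    def test_pre_window_diagnosis_alive_into_window_included(self):
        kept, tally = self.run(
            record(diag="1996-06-01", exit="2000-06-01", died=True)
        )
        assert len(kept) == 1 and tally["included"] == 1

    def test_record_fully_before_window_excluded(self):
        kept, tally = self.run(record(diag="1990-01-01", exit="1995-01-01", died=True))
        assert tally["outside_window"] == 1

    def test_corrupt_record_rejected(self):
        with pytest.raises(ValueError, match="corrupt"):
            self.run(record(diag="2000-01-01", exit="1999-01-01", died=False))


class TestCollapse:
    def test_anniversary_splitting(self):
        # survives exactly 2.5 years: person-time 1, 1, 0.5 in intervals 1-3
        rec = pd.DataFrame([record(
            diag="2000-01-01",
            exit=str(pd.Timestamp("2000-01-01") + pd.Timedelta(days=2.5 * DAYS_PER_YEAR)),
            died=True,
        )])
        cells = collapse_person_time(rec, flat_life_table(0.0), WINDOW)
        by_j = {j: y for j, y in zip(cells.interval, cells.y)}
        assert by_j[1] == pytest.approx(1.0, abs=1e-9)
        assert by_j[2] == pytest.approx(1.0, abs=1e-9)
        assert by_j[3] == pytest.approx(0.5, abs=1e-9)
        assert cells.d.sum() == 1 and cells.d[cells.interval == 3][0] == 1

    def test_zero_life_table_gives_zero_expected_deaths(self):
        rec = pd.DataFrame([record()])
        cells = collapse_person_time(rec, flat_life_table(0.0), WINDOW)
        assert np.all(cells.dstar == 0.0)

    def test_against_per_record_scalar_oracle(self):
        rng = np.random.default_rng(9)
        lt = flat_life_table(0.02)
        recs = []
        for k in range(20):
            diag = pd.Timestamp("1996-01-01") + pd.Timedelta(days=int(rng.integers(0, 4000)))
            dur = float(rng.uniform(1, 2600))
            died = bool(rng.uniform() < 0.5)
            recs.append(record(
                area=f"a{k % 3}", age=float(rng.uniform(30, 88)),
                diag=str(diag.date()), exit=str((diag + pd.Timedelta(days=dur)).date()),
                died=died,
            ))
        frame = pd.DataFrame(recs)
        cells = collapse_person_time(frame, lt, WINDOW, area_ids=["a0", "a1", "a2"])

        # independent scalar re-computation, record by record
        ws = pd.Timestamp(WINDOW[0]).toordinal()
        we = pd.Timestamp(WINDOW[1]).toordinal()
        total_py = {}
        total_ds = {}
        for _, r in frame.iterrows():
            diag = pd.Timestamp(r.diag_date).toordinal()
            exit_ = pd.Timestamp(r.exit_date).toordinal()
            stop = min(exit_, we, diag + 5 * DAYS_PER_YEAR)
            start = max(diag, ws)
            for j in range(1, 6):
                a = max(diag + (j - 1) * DAYS_PER_YEAR, start)
                b = min(diag + j * DAYS_PER_YEAR, stop)
                if b <= a:
                    continue
                key = (r.area_id, j)
                total_py[key] = total_py.get(key, 0.0) + (b - a) / DAYS_PER_YEAR
                total_ds[key] = total_ds.get(key, 0.0) + (b - a) / DAYS_PER_YEAR * 0.02
        got_py = {}
        got_ds = {}
        for j, i, y, ds in zip(cells.interval, cells.area_idx, cells.y, cells.dstar):
            key = (cells.area_ids[i], j)
            got_py[key] = got_py.get(key, 0.0) + y
            got_ds[key] = got_ds.get(key, 0.0) + ds
        assert set(got_py) == set(total_py)
        for key in total_py:
            assert got_py[key] == pytest.approx(total_py[key], abs=1e-6)
            assert got_ds[key] == pytest.approx(total_ds[key], abs=1e-6)

    def test_person_time_conserved(self):
        rng = np.random.default_rng(3)
        recs = []
        for k in range(30):
            diag = pd.Timestamp("1999-01-01") + pd.Timedelta(days=int(rng.integers(0, 2000)))
            dur = int(rng.integers(10, 2200))
            recs.append(record(diag=str(diag.date()),
                               exit=str((diag + pd.Timedelta(days=dur)).date()),
                               died=bool(rng.uniform() < 0.5)))
        frame = pd.DataFrame(recs)
        cells = collapse_person_time(frame, flat_life_table(0.01), WINDOW)
        diag = pd.to_datetime(frame.diag_date).map(pd.Timestamp.toordinal).to_numpy()
        exit_ = pd.to_datetime(frame.exit_date).map(pd.Timestamp.toordinal).to_numpy()
        stop = np.minimum.reduce([
            exit_.astype(float),
            np.full(len(frame), pd.Timestamp(WINDOW[1]).toordinal(), dtype=float),
            diag + 5 * DAYS_PER_YEAR,
        ])
        start = np.maximum(diag, pd.Timestamp(WINDOW[0]).toordinal())
        at_risk = np.maximum(stop - start, 0.0).sum() / DAYS_PER_YEAR
        assert cells.y.sum() == pytest.approx(at_risk, abs=1e-8)

    def test_expected_deaths_monotone_in_rates(self):
        rec = pd.DataFrame([record(), record(age=75.0, diag="2001-05-01", exit="2005-01-01")])
        lo = collapse_person_time(rec, flat_life_table(0.01), WINDOW)
        hi = collapse_person_time(rec, flat_life_table(0.03), WINDOW)
        assert np.all(hi.dstar >= lo.dstar)
        assert hi.dstar.sum() > lo.dstar.sum()

    def test_life_table_domain_violation_rejected(self):
        lt = flat_life_table(0.01, years=(1999, 2001))
        rec = pd.DataFrame([record(diag="2003-01-01", exit="2006-01-01")])
        with pytest.raises(ValueError, match="life-table"):
            collapse_person_time(rec, lt, WINDOW)


def test_broad_age_labels():
    assert broad_age_labels((0, 60, 70, 80)) == ("0-59", "60-69", "70-79", "80+")
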