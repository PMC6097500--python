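import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lekscale import data_prep
from lekscale.data_prep import (
    DateWindow,
    annualize_pdo,
    areal_disturbance,
    build_local_design,
    collapse_counts,
    disturbance_series,
    filter_records,
    group_density,
)


class TestFilterRecords:
    def test_each_rule(self, raw_counts):
        kept, report = filter_records(raw_counts)
        assert set(kept["lek_id"]) == {"A", "F"}
        assert report.malformed_date == 1
        assert report.before_start_year == 1
        assert report.unreliable_method == 1
        assert report.outside_window == 1
        assert report.unknown_sex == 1
        assert report.n_input == 7 and report.n_output == 2

    def test_may_20_excluded(self, raw_counts):
        kept, _ = filter_records(raw_counts)
        assert not ((kept["month"] == 5) & (kept["day"] > 7)).any()

    def test_window_boundaries_inclusive(self):
        rows = []
        for date in ("2000-04-01", "2000-05-07", "2000-03-31", "2000-05-08"):
            rows.append(dict(lek_id="A", group_id="G", date=date, n_males=3,
                             n_unknown=0, is_ground=True, is_checked=True,
                             in_survey=True))
        kept, _ = filter_records(pd.DataFrame(rows))
        assert len(kept) == 2

    def test_empty_input(self):
        kept, report = filter_records(pd.DataFrame(columns=[
            "lek_id", "group_id", "date", "n_males", "n_unknown",
            "is_ground", "is_checked", "in_survey"]))
        assert len(kept) == 0 and report.dropped() == 0

    def test_unknown_threshold_exact_boundary(self):
        # 5% exactly is excluded (>= threshold)
        row = dict(lek_id="A", group_id="G", date="2000-04-15", n_males=20,
                   n_unknown=1, is_ground=True, is_checked=True, in_survey=True)
        kept, _ = filter_records(pd.DataFrame([row]))
        assert len(kept) == 0

    def test_drop_counts_sum(self, raw_counts):
        kept, report = filter_records(raw_counts)
        assert report.dropped() == report.n_input - report.n_output

    @given(st.permutations(list(range(7))))
    @settings(max_examples=20, deadline=None)
    def test_order_invariance(self, perm):
        raw = pd.DataFrame([
            dict(lek_id=f"L{i}", group_id="G", date=d, n_males=m, n_unknown=u,
                 is_ground=g, is_checked=True, in_survey=True)
            for i, (d, m, u, g) in enumerate([
                ("2000-04-15", 10, 0, True), ("2000-05-20", 10, 0, True),
                ("2000-04-20", 10, 1, True), ("2000-04-20", 5, 0, False),
                ("1984-04-20", 5, 0, True), ("bad", 5, 0, True),
                ("2000-04-10", 0, 0, True)])
        ])
        shuffled = raw.iloc[list(perm)].reset_index(drop=True)
        kept, report = filter_records(shuffled)
        assert set(kept["lek_id"]) == {"L0", "L6"}
        assert report.dropped() == 5


class TestCollapseCounts:
    def _records(self, counts, lek="A", year=2000):
        return pd.DataFrame([
            dict(lek_id=lek, group_id="G", year=year, n_males=c) for c in counts
        ])

    def test_mean_exact(self):
        out = collapse_counts(self._records([12, 18, 15]), "mean")
        assert out["count"].iloc[0] == 15
        assert out["n_repeats"].iloc[0] == 3

    def test_half_to_even(self):
        assert collapse_counts(self._records([3, 2]), "mean")["count"].iloc[0] == 2
        assert collapse_counts(self._records([3, 4]), "mean")["count"].iloc[0] == 4

    def test_max(self):
        assert collapse_counts(self._records([12, 18, 15]), "max")["count"].iloc[0] == 18

    def test_max_geq_mean_everywhere(self):
        rng = np.random.default_rng(0)
        recs = pd.concat([
            self._records(rng.poisson(10, rng.integers(1, 5)), lek=f"L{i}",
                          year=2000 + i % 3)
            for i in range(30)
        ])
        mean = collapse_counts(recs, "mean").set_index(["lek_id", "year"])["count"]
        mx = collapse_counts(recs, "max").set_index(["lek_id", "year"])["count"]
        assert (mx >= mean).all()

    def test_bad_stat(self):
        with pytest.raises(ValueError, match="stat"):
            collapse_counts(self._records([1]), "median")


class TestAnnualizePdo:
    def test_constant_year(self):
        monthly = pd.DataFrame({"year": 2000, "month": range(1, 13), "value": 1.5})
        out = annualize_pdo(monthly)
        assert out["value"].iloc[0] == 1.5
        assert bool(out["complete"].iloc[0])

    def test_mean_of_1_to_12(self):
        monthly = pd.DataFrame(
            {"year": 2000, "month": range(1, 13), "value": range(1, 13)}
        )
        assert annualize_pdo(monthly)["value"].iloc[0] == pytest.approx(6.5)

    def test_incomplete_flagged(self):
        monthly = pd.DataFrame({"year": 2000, "month": range(1, 12), "value": 0.0})
        out = annualize_pdo(monthly)
        assert not bool(out["complete"].iloc[0])
        assert len(annualize_pdo(monthly, require_complete=True)) == 0

    def test_duplicate_month_raises(self):
        monthly = pd.DataFrame({"year": [2000, 2000], "month": [1, 1],
                                "value": [0.0, 1.0]})
        with pytest.raises(ValueError, match="duplicate"):
            annualize_pdo(monthly)


class TestArealDisturbance:
    def _pads(self, rows):
        return pd.DataFrame(rows, columns=["pad_id", "x_m", "y_m", "spud_year"])

    def test_no_pads(self):
        assert areal_disturbance((0, 0), self._pads([]), 3200, 2000) == 0.0

    def test_single_pad_closed_form(self):
        pads = self._pads([("p", 1000.0, 0.0, 1990)])
        got = areal_disturbance((0, 0), pads, 3200, 2000)
        assert got == pytest.approx((60 / 3200) ** 2)
        assert got == pytest.approx(3.515625e-4)

    def test_not_yet_constructed(self):
        pads = self._pads([("p", 100.0, 0.0, 2000)])
        assert areal_disturbance((0, 0), pads, 3200, 1999) == 0.0
        assert areal_disturbance((0, 0), pads, 3200, 2000) > 0

    def test_capped_at_one(self):
        pads = self._pads([(f"p{i}", 0.0, 0.0, 1990) for i in range(10000)])
        assert areal_disturbance((0, 0), pads, 100, 2000) == 1.0

    def test_radius_must_exceed_pad(self):
        with pytest.raises(ValueError):
            areal_disturbance((0, 0), self._pads([]), 50, 2000)

    def test_monotone_in_year(self):
        rng = np.random.default_rng(1)
        pads = self._pads([
            (f"p{i}", rng.uniform(-3000, 3000), rng.uniform(-3000, 3000),
             int(rng.integers(1990, 2010)))
            for i in range(50)
        ])
        vals = [areal_disturbance((0, 0), pads, 3200, y) for y in range(1985, 2015)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_single_pad_decreasing_in_radius(self):
        pads = self._pads([("p", 500.0, 0.0, 1990)])
        vals = [areal_disturbance((0, 0), pads, r, 2000)
                for r in (800, 1600, 3200, 6400)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_series_matches_pointwise(self):
        rng = np.random.default_rng(5)
        sites = pd.DataFrame({"lek_id": ["a", "b"], "group_id": "G",
                              "x_m": [0.0, 5000.0], "y_m": [0.0, 0.0]})
        pads = self._pads([
            (f"p{i}", rng.uniform(0, 6000), rng.uniform(-2000, 2000),
             int(rng.integers(1995, 2005)))
            for i in range(30)
        ])
        series = disturbance_series(sites, pads, (1600.0, 3200.0), range(1990, 2010))
        for _, row in series.sample(25, random_state=0).iterrows():
            site = sites.set_index("lek_id").loc[row["lek_id"]]
            expect = areal_disturbance(
                (site["x_m"], site["y_m"]), pads, row["radius_m"], row["year"]
            )
            assert row["proportion"] == pytest.approx(expect)


class TestGroupDensity:
    def _lek_years(self, counts, group="G", year=2000):
        return pd.DataFrame([
            dict(lek_id=f"L{i}", group_id=group, year=year, count=c, n_repeats=1)
            for i, c in enumerate(counts)
        ])

    def test_mean_of_two(self):
        out = group_density(self._lek_years([10, 20]))
        assert out["density"].iloc[0] == 15 and out["n_leks"].iloc[0] == 2

    def test_single_lek(self):
        out = group_density(self._lek_years([7]))
        assert out["density"].iloc[0] == 7 and out["n_leks"].iloc[0] == 1

    def test_zero_counts_included(self):
        out = group_density(self._lek_years([0, 0, 9]))
        assert out["density"].iloc[0] == pytest.approx(3.0)
        assert out["n_leks"].iloc[0] == 3

    def test_empty_group_year_absent(self):
        out = group_density(self._lek_years([5]))
        assert len(out) == 1  # nothing fabricated for other years


class TestBuildDesign:
    def test_standardized_columns(self, local_sim):
        design, consts = build_local_design(
            local_sim["lek_years"].drop(columns=["area_raw", "pdo_raw"]),
            local_sim["disturbance"], local_sim["pdo"], 3200.0, 1, 2,
        )
        for col in ("area", "pdo"):
            x = design[col].to_numpy()
            assert abs(x.mean()) < 1e-10
            assert abs(x.std(ddof=1) - 1) < 1e-10

    def test_lag_join_alignment(self, local_sim):
        design, _ = build_local_design(
            local_sim["lek_years"].drop(columns=["area_raw", "pdo_raw"]),
            local_sim["disturbance"], local_sim["pdo"], 3200.0, 1, 1,
        )
        dist = local_sim["disturbance"].set_index(["lek_id", "year"])["proportion"]
        row = design.iloc[10]
        assert row["area_raw"] == pytest.approx(
            dist.loc[(row["lek_id"], row["year"] - 1)]
        )

    def test_constant_predictor_raises(self, local_sim):
        dist = local_sim["disturbance"].assign(proportion=0.25)
        with pytest.raises(ValueError, match="area"):
            build_local_design(
                local_sim["lek_years"].drop(columns=["area_raw", "pdo_raw"]),
                dist, local_sim["pdo"], 3200.0, 1, 1,
            )

    def test_standardize_toy(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        s = data_prep._standardize(df, "v", "v_std")
        assert list(df["v_std"]) == [-1.0, 0.0, 1.0]
        assert s.mean == 2.0 and s.sd == 1.0
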