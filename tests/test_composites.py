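"""Composite analysis: group means, permutation t-test, Hotelling T²."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from palmclim.composites import (
    SEASONS,
    composite_maps,
    composite_timeseries,
    hotelling_t2,
    window_months,
)
from palmclim.variability import YieldRecord


def _record(labels, start=1990):
    labels = np.asarray(labels, dtype=str)
    n = len(labels)
    rate = np.where(labels == "low", -5.0, np.where(labels == "high", 5.0, 0.0))
    return YieldRecord(
        region="test",
        years=np.arange(start, start + n),
        yields=np.full(n, 18.0),
        trend=np.full(n, 18.0),
        rate=rate,
        labels=labels,
        threshold=3.0,
    )


def _span_series(record, rng=None, values=None):
    first = int(record.years[0]) - 3
    last = int(record.years[-1])
    idx = pd.period_range(f"{first}-01", f"{last}-12", freq="M")
    if values is None:
        values = rng.standard_normal(len(idx))
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestCompositeTimeseries:
    def test_identical_windows_give_zero_deviation_and_p_one(self):
        # a purely seasonal series repeats exactly in every year's window
        record = _record(["low"] * 3 + ["normal"] * 3 + ["high"] * 3)
        n_months = (len(record.years) + 3) * 12
        cycle = np.tile(np.sin(2 * np.pi * np.arange(12) / 12), n_months // 12)
        series = _span_series(record, values=cycle)
        res = composite_timeseries(series, record, n_perm=300, seed=0)
        np.testing.assert_allclose(res.mean_low, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.mean_high, 0.0, atol=1e-12)
        assert res.pvalue.min() == pytest.approx(1.0)

    def test_constructed_group_shift_detected_at_harvest_month(self, rng):
        record = _record(["low"] * 5 + ["normal"] * 2 + ["high"] * 5)
        series = _span_series(record, rng=rng) * 0.3
        # inject a group contrast in March of each labelled harvest year
        for y in record.low_years:
            series.loc[pd.Period(f"{y}-03", freq="M")] -= 4.0
        for y in record.high_years:
            series.loc[pd.Period(f"{y}-03", freq="M")] += 4.0
        res = composite_timeseries(series, record, n_perm=500, seed=1)
        mar0 = 36 + 2
        assert res.pvalue[mar0] < 0.05
        assert res.mean_high[mar0] - res.mean_low[mar0] > 4.0

    def test_pvalues_match_exhaustive_enumeration(self, rng):
        # 6 low + 6 high years: all C(12,6) label assignments enumerable
        record = _record(["low"] * 6 + ["high"] * 6)
        series = _span_series(record, rng=rng)
        n_perm = 2000
        res = composite_timeseries(series, record, n_perm=n_perm, seed=2)

        # oracle extracts each year's window with its own period arithmetic
        X = np.array(
            [series.loc[window_months(int(y))].to_numpy() for y in record.years]
        )

        def tstat(a, b):
            sp2 = (
                a.var(0, ddof=1) * (len(a) - 1) + b.var(0, ddof=1) * (len(b) - 1)
            ) / (len(a) + len(b) - 2)
            return (a.mean(0) - b.mean(0)) / np.sqrt(sp2 * (2.0 / 6.0))

        t_obs = np.abs(tstat(X[:6], X[6:]))
        combos = list(combinations(range(12), 6))
        exact = np.zeros(48)
        for combo in combos:
            sel = np.zeros(12, dtype=bool)
            sel[list(combo)] = True
            exact += np.abs(tstat(X[sel], X[~sel])) >= t_obs - 1e-12
        exact /= len(combos)
        tol = 2.0 / np.sqrt(n_perm)
        assert np.max(np.abs(res.pvalue - exact)) <= tol + 1.0 / n_perm

    def test_label_swap_negates_means_keeps_pvalues(self, rng):
        labels = np.array(
            ["low"] * 4 + ["normal"] * 3 + ["high"] * 5
        )
        record = _record(labels)
        series = _span_series(record, rng=rng)
        res = composite_timeseries(series, record, n_perm=400, seed=3)
        swapped = np.where(
            labels == "low", "high", np.where(labels == "high", "low", "normal")
        )
        res2 = composite_timeseries(series, _record(swapped), n_perm=400, seed=3)
        np.testing.assert_allclose(res.mean_low, res2.mean_high, atol=1e-12)
        np.testing.assert_allclose(res.mean_high, res2.mean_low, atol=1e-12)
        np.testing.assert_allclose(res.pvalue, res2.pvalue, atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        record = _record(["low"] * 4 + ["high"] * 4)
        series = _span_series(record, rng=rng)
        a = composite_timeseries(series, record, n_perm=200, seed=9)
        b = composite_timeseries(series, record, n_perm=200, seed=9)
        np.testing.assert_array_equal(a.pvalue, b.pvalue)

    def test_small_group_rejected(self, rng):
        record = _record(["low"] + ["normal"] * 6 + ["high"] * 3)
        series = _span_series(record, rng=rng)
        with pytest.raises(ValueError):
            composite_timeseries(series, record, n_perm=100, seed=0)


class TestHotelling:
    def test_zero_difference_gives_zero_statistic(self, rng):
        a = rng.standard_normal((6, 2))
        assert hotelling_t2(a, a.copy()) == pytest.approx(0.0, abs=1e-20)

    def test_matches_definition_on_random_samples(self, rng):
        a = rng.standard_normal((7, 2))
        b = rng.standard_normal((6, 2)) + 0.5
        d = a.mean(0) - b.mean(0)
        sp = (6 * np.cov(a.T) + 5 * np.cov(b.T)) / 11
        expected = (7 * 6 / 13) * d @ np.linalg.inv(sp) @ d
        assert hotelling_t2(a, b) == pytest.approx(expected, rel=1e-12)


def _season_field(record, season, per_year, lats, lons, fill=0.0):
    """Field whose values in the given season of each year are per_year[y]."""
    first = int(record.years[0]) - 3
    last = int(record.years[-1])
    time = pd.date_range(f"{first}-01-01", f"{last}-12-01", freq="MS")
    vals = np.full((len(time), len(lats), len(lons)), fill)
    tindex = pd.DatetimeIndex(time).to_period("M")
    for y in record.years:
        months = pd.PeriodIndex(
            [pd.Period(year=int(y) + off, month=m, freq="M")
             for m, off in SEASONS[season]]
        )
        vals[tindex.isin(months)] = per_year[int(y)]
    return xr.DataArray(
        vals, coords={"time": time, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
    )


class TestCompositeMaps:
    lats = np.arange(0.0, 4.1, 1.0)
    lons = np.arange(100.0, 104.1, 1.0)

    def test_year_invariant_vector_field_gives_t2_zero_p_one(self, rng):
        record = _record(["low"] * 4 + ["high"] * 4)
        shared = rng.standard_normal((len(self.lats), len(self.lons)))
        per = {int(y): shared for y in record.years}
        u = _season_field(record, "DJF", per, self.lats, self.lons)
        res = composite_maps((u, u.copy()), record, seasons=("DJF",), n_perm=150, seed=0)
        np.testing.assert_allclose(res["DJF"].mean_low, res["DJF"].mean_high, atol=1e-12)
        assert np.all(res["DJF"].pvalue == pytest.approx(1.0))

    def test_zonal_only_shift_flagged_by_t2_not_meridional_t(self, rng):
        record = _record(["low"] * 6 + ["high"] * 6)
        u_per, v_per = {}, {}
        shape = (len(self.lats), len(self.lons))
        for y in record.years:
            shift = 3.0 if y in record.high_years else -3.0
            u_per[int(y)] = shift + 0.3 * rng.standard_normal(shape)
            v_per[int(y)] = 0.3 * rng.standard_normal(shape)
        u = _season_field(record, "DJF", u_per, self.lats, self.lons)
        v = _season_field(record, "DJF", v_per, self.lats, self.lons)
        res_vec = composite_maps((u, v), record, seasons=("DJF",), n_perm=400, seed=1)
        res_v = composite_maps(v, record, seasons=("DJF",), n_perm=400, seed=1)
        assert np.mean(res_vec["DJF"].pvalue < 0.05) > 0.9
        assert np.mean(res_v["DJF"].pvalue < 0.05) < 0.3

    def test_scalar_null_rejection_rate_near_level(self, rng):
        # many independent null cells within one run stand in for
        # replicate datasets; rejection at 95% should sit near 5%
        record = _record(["low"] * 6 + ["high"] * 6)
        lats = np.arange(0.0, 9.1, 1.0)
        lons = np.arange(100.0, 119.1, 1.0)
        per = {int(y): rng.standard_normal((len(lats), len(lons)))
               for y in record.years}
        field = _season_field(record, "MAM", per, lats, lons)
        res = composite_maps(field, record, seasons=("MAM",), n_perm=800, seed=4)
        rate = float(np.mean(res["MAM"].pvalue < 0.05))
        assert 0.005 <= rate <= 0.12

    def test_season_windows_relative_to_harvest_year(self, rng):
        # SON belongs to the year before harvest: a signal placed in
        # Sep-Nov of year y-1 must surface in year y's SON-1 composite
        record = _record(["low"] * 3 + ["high"] * 3)
        per = {int(y): (5.0 if y in record.high_years else -5.0) * np.ones((2, 2))
               for y in record.years}
        field = _season_field(record, "SON-1", per, np.arange(2.0), np.arange(2.0))
        res = composite_maps(field, record, seasons=("SON-1",), n_perm=200, seed=0)
        assert np.all(res["SON-1"].mean_high - res["SON-1"].mean_low > 9.0)

    def test_missing_season_rejected(self, rng):
        record = _record(["low"] * 3 + ["high"] * 3)
        per = {int(y): rng.standard_normal((2, 2)) for y in record.years}
        field = _season_field(record, "DJF", per, np.arange(2.0), np.arange(2.0))
        field = field.isel(time=slice(40, None))
        with pytest.raises(ValueError):
            composite_maps(field, record, seasons=("SON-1",), n_perm=100, seed=0)
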