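"""Derived climate variables against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from palmclim.derived import (
    PenmanInputs,
    SatVapConstants,
    box_sst_index,
    integrated_moisture_flux,
    monsoon_index,
    preprocess,
    reference_evapotranspiration,
    regional_mean,
    relative_humidity,
    saturation_vapour_pressure,
    wind_2m_from_10m,
)

C = SatVapConstants()


def _field(values, lats, lons, start="1987-01-01"):
    time = pd.date_range(start, periods=values.shape[0], freq="MS")
    return xr.DataArray(
        values, coords={"time": time, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
    )


class TestSaturationVapourPressure:
    def test_reference_temperature_returns_a1(self):
        assert saturation_vapour_pressure(273.16) == pytest.approx(6.1121, abs=0)

    def test_matches_direct_closed_form(self):
        T = 293.15
        expected = 6.1121 * np.exp(17.502 * (T - 273.16) / (T - 32.19))
        assert saturation_vapour_pressure(T) == pytest.approx(expected, rel=1e-14)

    def test_monotone_increasing(self):
        T = np.linspace(230.0, 320.0, 200)
        e = saturation_vapour_pressure(T)
        assert np.all(np.diff(e) > 0)

    def test_domain_error_below_a4(self):
        with pytest.raises(ValueError):
            saturation_vapour_pressure(30.0)


class TestRelativeHumidity:
    def test_saturated_air_is_100_percent(self):
        assert relative_humidity(300.0, 300.0) == pytest.approx(100.0, abs=0)

    def test_dew_point_below_temperature_is_subsaturated(self):
        assert relative_humidity(300.0, 295.0) < 100.0

    def test_matches_two_step_oracle(self):
        T, Td = 300.0, 295.0
        esat = lambda t: 6.1121 * np.exp(17.502 * (t - 273.16) / (t - 32.19))
        assert relative_humidity(T, Td) == pytest.approx(
            100.0 * esat(Td) / esat(T), rel=1e-14
        )

    def test_invariant_under_a1_rescaling(self):
        scaled = SatVapConstants(a1=C.a1 * 731.5)
        assert relative_humidity(302.0, 296.0, scaled) == pytest.approx(
            relative_humidity(302.0, 296.0), rel=1e-14
        )


class TestWindConversion:
    def test_zero_maps_to_zero(self):
        assert wind_2m_from_10m(0.0) == 0.0

    def test_unit_wind_scale_factor(self):
        assert wind_2m_from_10m(1.0) == pytest.approx(4.87 / np.log(672.58), rel=1e-14)

    def test_linearity(self):
        assert wind_2m_from_10m(6.4) == pytest.approx(2 * wind_2m_from_10m(3.2))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            wind_2m_from_10m(-0.1)


class TestReferenceEvapotranspiration:
    def test_no_energy_no_vapour_deficit_gives_zero(self):
        inp = PenmanInputs(Rn=5.0, G=5.0, T=25.0, u2=2.0, es=2.0, ea=2.0,
                           Delta=0.19, gamma=0.067)
        assert reference_evapotranspiration(inp) == 0.0

    def test_toy_day_matches_hand_evaluation(self):
        inp = PenmanInputs(Rn=13.28, G=0.0, T=25.0, u2=2.0, es=3.0, ea=2.0,
                           Delta=0.189, gamma=0.0674)
        expected = (
            0.408 * 0.189 * 13.28 + 0.0674 * (900.0 / (25.0 + 273.0)) * 2.0 * 1.0
        ) / (0.189 + 0.0674 * (1.0 + 0.34 * 2.0))
        assert reference_evapotranspiration(inp) == pytest.approx(expected, rel=1e-14)

    def test_increases_with_vapour_deficit(self):
        base = dict(Rn=13.28, G=0.0, T=25.0, u2=2.0, ea=1.5, Delta=0.189, gamma=0.0674)
        lo = reference_evapotranspiration(PenmanInputs(es=2.0, **base))
        hi = reference_evapotranspiration(PenmanInputs(es=2.5, **base))
        assert hi > lo

    def test_nonnegative_when_energy_and_deficit_nonnegative(self, rng):
        for _ in range(50):
            inp = PenmanInputs(
                Rn=rng.uniform(0, 20), G=0.0, T=rng.uniform(15, 35),
                u2=rng.uniform(0, 6), es=2.0 + rng.uniform(0, 2), ea=2.0,
                Delta=rng.uniform(0.1, 0.3), gamma=rng.uniform(0.05, 0.08),
            )
            assert reference_evapotranspiration(inp) >= 0.0


class TestMoistureFlux:
    def test_constant_profile(self):
        p = np.linspace(100000.0, 25000.0, 21)
        q = np.full(21, 0.01)
        w = np.full(21, 5.0)
        expected = 5.0 * 0.01 * (100000.0 - 25000.0) / 9.807
        assert integrated_moisture_flux(q, w, p) == pytest.approx(expected, rel=1e-14)

    def test_zero_humidity_gives_zero_flux(self):
        p = np.linspace(100000.0, 25000.0, 21)
        assert integrated_moisture_flux(np.zeros(21), np.ones(21), p) == 0.0

    def test_random_profile_matches_trapezoid_oracle(self, rng):
        p = np.sort(rng.uniform(26000, 101000, 21))[::-1].copy()
        q = rng.uniform(0, 0.02, 21)
        w = rng.uniform(-10, 10, 21)
        oracle = sum(
            0.5 * (w[k] * q[k] + w[k + 1] * q[k + 1]) * (p[k] - p[k + 1])
            for k in range(20)
        ) / 9.807
        assert integrated_moisture_flux(q, w, p) == pytest.approx(oracle, rel=1e-12)

    def test_linear_in_humidity_and_wind(self, rng):
        p = np.linspace(100000.0, 25000.0, 21)
        q = rng.uniform(0, 0.02, 21)
        w = rng.uniform(-10, 10, 21)
        f = integrated_moisture_flux(q, w, p)
        assert integrated_moisture_flux(3 * q, w, p) == pytest.approx(3 * f)
        assert integrated_moisture_flux(q, -2 * w, p) == pytest.approx(-2 * f)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            integrated_moisture_flux([0.01], [1.0], [100000.0])
        p_bad = np.array([100000.0, 50000.0, 60000.0])
        with pytest.raises(ValueError):
            integrated_moisture_flux(np.ones(3), np.ones(3), p_bad)


class TestMonsoonIndex:
    lats = np.arange(0.0, 15.1, 2.5)
    lons = np.arange(80.0, 125.1, 2.5)

    def test_zero_anomalies_give_zero(self):
        u = _field(np.zeros((3, len(self.lats), len(self.lons))), self.lats, self.lons)
        idx = monsoon_index(u, u)
        assert np.allclose(idx.to_numpy(), 0.0)

    def test_unit_zonal_anomaly(self):
        u = _field(np.ones((3, len(self.lats), len(self.lons))), self.lats, self.lons)
        v = _field(np.zeros((3, len(self.lats), len(self.lons))), self.lats, self.lons)
        assert np.allclose(monsoon_index(u, v).to_numpy(), 1.0)

    def test_matches_weighted_box_oracle(self, rng):
        shape = (4, len(self.lats), len(self.lons))
        u = _field(rng.standard_normal(shape), self.lats, self.lons)
        v = _field(rng.standard_normal(shape), self.lats, self.lons)
        idx = monsoon_index(u, v)

        def boxmean(da, latr, lonr, t):
            sel = da.sel(lat=slice(*latr), lon=slice(*lonr)).isel(time=t).values
            w = np.cos(np.deg2rad(da.sel(lat=slice(*latr)).lat.values))
            return np.average(sel, axis=0, weights=w).mean()

        for t in range(4):
            oracle = boxmean(u, (7.5, 12.5), (85, 95), t) - boxmean(
                v, (0, 8.75), (120, 122.5), t
            )
            assert idx.iloc[t] == pytest.approx(oracle, rel=1e-12)


class TestBoxIndexAndRegionalMean:
    def test_uniform_anomaly_recovered(self):
        lats = np.arange(-10.0, 10.1, 2.0)
        lons = np.arange(200.0, 280.1, 5.0)
        sst = _field(np.full((3, len(lats), len(lons)), 0.5), lats, lons)
        idx = box_sst_index(sst, (-5, 5), (210, 270), name="NINO3")
        assert np.allclose(idx.to_numpy(), 0.5)
        assert idx.name == "NINO3"

    def test_box_outside_grid_rejected(self):
        lats = np.arange(-10.0, 10.1, 2.0)
        lons = np.arange(200.0, 280.1, 5.0)
        sst = _field(np.zeros((3, len(lats), len(lons))), lats, lons)
        with pytest.raises(ValueError):
            box_sst_index(sst, (40, 50), (0, 10), name="bad")

    def test_regional_mean_single_cell_mask(self, rng):
        lats = np.arange(0.0, 5.1, 1.0)
        lons = np.arange(100.0, 105.1, 1.0)
        field = _field(rng.standard_normal((6, len(lats), len(lons))), lats, lons)
        mask = xr.zeros_like(field.isel(time=0), dtype=bool)
        mask[2, 3] = True
        got = regional_mean(field, mask)
        np.testing.assert_allclose(got.to_numpy(), field.values[:, 2, 3])

    def test_regional_mean_matches_hand_weighted_mean(self, rng):
        lats = np.arange(0.0, 5.1, 1.0)
        lons = np.arange(100.0, 105.1, 1.0)
        field = _field(rng.standard_normal((2, len(lats), len(lons))), lats, lons)
        mask = xr.zeros_like(field.isel(time=0), dtype=bool)
        cells = [(0, 0), (1, 4), (3, 2), (5, 5), (4, 1)]
        for i, j in cells:
            mask[i, j] = True
        got = regional_mean(field, mask)
        w = np.array([np.cos(np.deg2rad(lats[i])) for i, _ in cells])
        for t in range(2):
            vals = np.array([field.values[t, i, j] for i, j in cells])
            assert got.iloc[t] == pytest.approx(np.sum(w * vals) / np.sum(w), rel=1e-12)

    def test_empty_mask_rejected(self, rng):
        lats = np.arange(0.0, 3.1, 1.0)
        field = _field(rng.standard_normal((2, len(lats), 4)), lats, np.arange(4.0))
        mask = xr.zeros_like(field.isel(time=0), dtype=bool)
        with pytest.raises(ValueError):
            regional_mean(field, mask)


class TestPreprocess:
    def test_linear_series_detrends_to_zero(self):
        idx = pd.period_range("1987-01", periods=120, freq="M")
        series = pd.Series(np.linspace(0, 10, 120), index=idx)
        out = preprocess(series)
        assert np.max(np.abs(out.to_numpy())) < 1e-9

    def test_pure_seasonal_cycle_removed(self):
        idx = pd.period_range("1987-01", periods=120, freq="M")
        cycle = np.tile(np.sin(2 * np.pi * np.arange(12) / 12), 10)
        out = preprocess(pd.Series(cycle, index=idx))
        assert np.max(np.abs(out.to_numpy())) < 1e-9

    def test_matches_two_step_oracle(self, rng):
        idx = pd.period_range("1987-01", periods=240, freq="M")
        months = idx.month.to_numpy()
        x = np.zeros(240)
        for t in range(1, 240):
            x[t] = 0.6 * x[t - 1] + rng.standard_normal()
        series = pd.Series(
            x + 0.01 * np.arange(240) + 2.0 * np.cos(2 * np.pi * months / 12), index=idx
        )
        got = preprocess(series).to_numpy()
        # independent oracle: explicit OLS on month dummies + centred trend
        import statsmodels.api as sm

        D = pd.get_dummies(pd.Categorical(months)).to_numpy(dtype=float)
        t = np.arange(240.0)
        Z = np.column_stack([D, t - t.mean()])
        resid = sm.OLS(series.to_numpy(), Z).fit().resid
        np.testing.assert_allclose(got, resid, atol=1e-9)
        # and the classical two-step version (climatology, then polyfit
        # residual) agrees closely, though not to rounding
        vals = series.to_numpy().copy()
        for m in range(1, 13):
            vals[months == m] -= series.to_numpy()[months == m].mean()
        twostep = vals - np.polyval(np.polyfit(t, vals, 1), t)
        assert np.corrcoef(got, twostep)[0, 1] > 0.999

    def test_idempotent_on_full_span_baseline(self, rng):
        idx = pd.period_range("1987-01", periods=180, freq="M")
        series = pd.Series(rng.standard_normal(180), index=idx)
        once = preprocess(series)
        twice = preprocess(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)

    def test_field_roundtrip_matches_series_path(self, rng):
        lats = np.arange(0.0, 3.1, 1.0)
        lons = np.arange(100.0, 102.1, 1.0)
        vals = rng.standard_normal((120, len(lats), len(lons)))
        field = _field(vals, lats, lons)
        anom = preprocess(field)
        # each grid point should match the 1-D series treatment
        idx = pd.period_range("1987-01", periods=120, freq="M")
        series = pd.Series(vals[:, 1, 2], index=idx)
        np.testing.assert_allclose(
            anom.values[:, 1, 2], preprocess(series).to_numpy(), atol=1e-8
        )

    def test_smoothing_preserves_length(self, rng):
        idx = pd.period_range("1987-01", periods=60, freq="M")
        series = pd.Series(rng.standard_normal(60), index=idx)
        out = preprocess(series, smooth=True)
        assert len(out) == 60
        # interior points are true 3-month means of the unsmoothed anomalies
        raw = preprocess(series).to_numpy()
        assert out.iloc[10] == pytest.approx(raw[9:12].mean())

    def test_disjoint_baseline_rejected(self):
        idx = pd.period_range("1987-01", periods=24, freq="M")
        series = pd.Series(np.arange(24.0), index=idx)
        with pytest.raises(ValueError):
            preprocess(series, baseline=(2000, 2010))
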