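"""Derived climate variables and preprocessing.

Covers every quantity the analysis derives from raw monthly fields:

* near-surface humidity — saturation vapour pressure (Buck/ECMWF form)
  and relative humidity from air and dew-point temperature;
* FAO56 reference crop evapotranspiration (Penman–Monteith) with the
  standard 10 m → 2 m log-profile wind conversion;
* vertically integrated moisture flux between the surface and 250 hPa;
* climate indices: cos-latitude-weighted box means of SST anomalies
  (Niño3, Ningaloo, Modoki-style boxes) and the 850 hPa monsoon index;
* the anomaly / detrend / 3-month-running-mean preprocessing applied to
  all series before correlation and composite analysis.

Gridded monthly fields are :class:`xarray.DataArray` objects with dims
``(time, lat, lon)`` and a monthly datetime coordinate; scalar monthly
indices are :class:`pandas.Series` with a monthly ``PeriodIndex``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "SatVapConstants",
    "PenmanInputs",
    "saturation_vapour_pressure",
    "relative_humidity",
    "wind_2m_from_10m",
    "svp_slope",
    "psychrometric_constant",
    "reference_evapotranspiration",
    "integrated_moisture_flux",
    "box_mean",
    "box_sst_index",
    "monsoon_index",
    "preprocess",
    "regrid_like",
    "regional_mean",
]

GRAVITY = 9.807  # m s-2, fixed for the moisture-flux integral


@dataclass(frozen=True)
class SatVapConstants:
    """Constants of the saturation-vapour-pressure exponential.

    The default values give pressure in hPa (the a1 unit); the ratio
    used for relative humidity is unit-free so the choice of hPa vs Pa
    never propagates downstream.
    """

    a1: float = 6.1121  # hPa
    a3: float = 17.502  # dimensionless
    a4: float = 32.19  # K
    T0: float = 273.16  # K


DEFAULT_SVP = SatVapConstants()


def saturation_vapour_pressure(T, constants: SatVapConstants = DEFAULT_SVP):
    """Saturation vapour pressure (hPa) over water at temperature ``T`` (K).

    e_sat(T) = a1 * exp(a3 * (T - T0) / (T - a4)).  Valid only for
    T > a4 (≈32 K), far below any physical near-surface temperature.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= constants.a4):
        raise ValueError(f"temperature must exceed a4 = {constants.a4} K")
    out = constants.a1 * np.exp(constants.a3 * (T - constants.T0) / (T - constants.a4))
    return out if out.ndim else float(out)


def relative_humidity(T, Td, constants: SatVapConstants = DEFAULT_SVP):
    """Relative humidity (%) from air and dew-point temperature (K).

    RH = 100 * e_sat(Td) / e_sat(T).  Values above 100% (possible with
    reanalysis-style inputs where Td > T) are reported as-is and logged.
    """
    ratio = np.asarray(saturation_vapour_pressure(Td, constants)) / np.asarray(
        saturation_vapour_pressure(T, constants)
    )
    rh = 100.0 * ratio
    if np.any(rh > 100.0 + 1e-9):
        logger.info(
            "relative humidity exceeds 100%% at %d points (max %.2f%%); left unclipped",
            int(np.sum(rh > 100.0)), float(np.max(rh)),
        )
    return rh if rh.ndim else float(rh)


def wind_2m_from_10m(u10):
    """FAO56 log-profile conversion of 10 m wind speed to 2 m (m s-1).

    u2 = u10 * 4.87 / ln(67.8 * 10 - 5.42), a fixed factor of ~0.748.
    """
    u10 = np.asarray(u10, dtype=float)
    if np.any(u10 < 0):
        raise ValueError("wind speed must be non-negative")
    out = u10 * 4.87 / np.log(67.8 * 10.0 - 5.42)
    return out if out.ndim else float(out)


def svp_slope(T_celsius):
    """Slope of the saturation-vapour-pressure curve Δ (kPa °C-1), FAO56 Eq. 13."""
    T = np.asarray(T_celsius, dtype=float)
    es = 0.6108 * np.exp(17.27 * T / (T + 237.3))
    out = 4098.0 * es / (T + 237.3) ** 2
    return out if out.ndim else float(out)


def psychrometric_constant(pressure_kpa=101.3):
    """Psychrometric constant γ (kPa °C-1), FAO56 Eq. 8: γ = 0.000665 * P."""
    out = 0.000665 * np.asarray(pressure_kpa, dtype=float)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PenmanInputs:
    """Daily inputs to the FAO56 Penman–Monteith reference ET equation.

    Units: Rn, G in MJ m-2 d-1; T in °C; u2 in m s-1; es, ea in kPa;
    Delta, gamma in kPa °C-1.  Soil heat flux G defaults to 0, the FAO56
    convention for daily time steps.
    """

    Rn: float
    T: float
    u2: float
    es: float
    ea: float
    Delta: float
    gamma: float
    G: float = 0.0


def reference_evapotranspiration(inputs: PenmanInputs):
    """FAO56 Penman–Monteith reference crop evapotranspiration (mm d-1).

    ET0 = [0.408 Δ (Rn - G) + γ (900/(T+273)) u2 (es - ea)]
          / [Δ + γ (1 + 0.34 u2)]
    """
    arrs = {k: np.asarray(getattr(inputs, k), dtype=float)
            for k in ("Rn", "G", "T", "u2", "es", "ea", "Delta", "gamma")}
    if any(not np.all(np.isfinite(v)) for v in arrs.values()):
        raise ValueError("Penman-Monteith inputs must be finite")
    denom = arrs["Delta"] + arrs["gamma"] * (1.0 + 0.34 * arrs["u2"])
    if np.any(denom <= 0):
        raise ValueError("Delta + gamma*(1 + 0.34 u2) must be positive")
    num = 0.408 * arrs["Delta"] * (arrs["Rn"] - arrs["G"]) + arrs["gamma"] * (
        900.0 / (arrs["T"] + 273.0)
    ) * arrs["u2"] * (arrs["es"] - arrs["ea"])
    out = num / denom
    return out if out.ndim else float(out)


def integrated_moisture_flux(q, wind, pressures, g: float = GRAVITY):
    """Vertically integrated moisture flux (kg m-1 s-1) for one wind component.

    Mass-weighted trapezoidal sum of W*q over pressure layers between the
    surface and the top level (250 hPa in the standard configuration):
    each layer contributes mean(Wq_k, Wq_{k+1}) * (p_k - p_{k+1}) / g.

    Parameters
    ----------
    q, wind : arrays with the pressure level as the FIRST axis
        Specific humidity (kg kg-1) and one wind component (m s-1).
    pressures : array, same level axis
        Level pressures in Pa, strictly decreasing from the surface up.
        May carry extra trailing dims matching q/wind (per-column surface
        pressure) or be one-dimensional.
    """
    q = np.asarray(q, dtype=float)
    wind = np.asarray(wind, dtype=float)
    p = np.asarray(pressures, dtype=float)
    if q.shape[0] < 2:
        raise ValueError("need at least 2 pressure levels")
    if q.shape != wind.shape or p.shape[0] != q.shape[0]:
        raise ValueError("q, wind and pressures must share the level axis")
    dp = p[:-1] - p[1:]
    if np.any(dp <= 0):
        raise ValueError("pressures must be strictly decreasing from the surface")
    wq = wind * q
    layer = 0.5 * (wq[:-1] + wq[1:])
    out = np.sum(layer * dp, axis=0) / g
    return out if np.ndim(out) else float(out)


def _coslat_weights(lat):
    w = np.cos(np.deg2rad(np.asarray(lat, dtype=float)))
    if np.any(w < 0):
        raise ValueError("latitudes outside [-90, 90]")
    return w


def box_mean(field: xr.DataArray, lat_range, lon_range) -> pd.Series:
    """Cos-latitude-weighted spatial mean of a monthly field over a box.

    Returns a monthly :class:`pandas.Series` (PeriodIndex).
    """
    sub = field.sel(
        lat=slice(min(lat_range), max(lat_range)),
        lon=slice(min(lon_range), max(lon_range)),
    )
    if sub.lat.size == 0 or sub.lon.size == 0:
        raise ValueError(
            f"box lat={lat_range}, lon={lon_range} does not intersect the grid"
        )
    w = xr.DataArray(_coslat_weights(sub.lat), coords={"lat": sub.lat}, dims="lat")
    mean = sub.weighted(w).mean(dim=("lat", "lon"))
    idx = pd.DatetimeIndex(mean.time.values).to_period("M")
    return pd.Series(mean.values, index=idx)


def box_sst_index(sst: xr.DataArray, lat_range, lon_range, name: str) -> pd.Series:
    """Named SST box index (e.g. Niño3, Ningaloo) from an SST anomaly field."""
    out = box_mean(sst, lat_range, lon_range)
    out.name = name
    return out


# monsoon index boxes: 850 hPa zonal wind over the Bay of Bengal minus
# meridional wind east of the Philippines
ICMI_U_BOX = ((7.5, 12.5), (85.0, 95.0))
ICMI_V_BOX = ((0.0, 8.75), (120.0, 122.5))


def monsoon_index(
    u850: xr.DataArray,
    v850: xr.DataArray,
    u_box=ICMI_U_BOX,
    v_box=ICMI_V_BOX,
) -> pd.Series:
    """Monsoon circulation index from 850 hPa wind anomalies.

    ICMI(t) = area-mean zonal wind anomaly over ``u_box`` minus area-mean
    meridional wind anomaly over ``v_box``; both fields must already be
    deseasonalized.  Captures the seasonal reversal of the low-level flow
    over the Malaysian region.
    """
    u = box_mean(u850, *u_box)
    v = box_mean(v850, *v_box)
    out = u - v
    out.name = "ICMI"
    return out


def _anomaly_detrend_core(
    values: np.ndarray,
    months: np.ndarray,
    in_base: np.ndarray,
    detrend: bool,
) -> np.ndarray:
    """Joint least-squares removal of monthly climatology and linear trend.

    ``values`` is (time, points).  The climatology (12 month-dummy
    coefficients) and, when requested, the linear trend are estimated in
    ONE least-squares fit over the baseline rows and subtracted from all
    rows.  With the baseline equal to the full span this is an
    orthogonal projection: exactly idempotent, and exactly zero on a
    pure trend or a pure seasonal cycle.
    """
    n = len(months)
    dummies = (months[:, None] == np.arange(1, 13)[None, :]).astype(float)
    if detrend:
        t = np.arange(n, dtype=float)
        Z = np.column_stack([dummies, t - t.mean()])
    else:
        Z = dummies
    coef, *_ = np.linalg.lstsq(Z[in_base], values[in_base], rcond=None)
    return values - Z @ coef


def preprocess(
    obj,
    baseline: tuple[int, int] | None = None,
    smooth: bool = False,
    detrend: bool = True,
):
    """Anomaly / detrend / running-mean preprocessing.

    Subtract the per-calendar-month climatology estimated over the
    ``baseline`` year range (default: the full span) and remove a
    per-point least-squares linear trend; the two are estimated jointly
    in a single least-squares fit, so on a full-span baseline the
    operation is an orthogonal projection (idempotent to rounding).
    Optionally apply a centred 3-month running mean (endpoints use the
    available shortened window so series length is preserved for lag
    bookkeeping).

    Works on monthly :class:`pandas.Series` (PeriodIndex) and on
    ``(time, lat, lon)`` :class:`xarray.DataArray` fields.
    """
    if isinstance(obj, pd.Series):
        if not isinstance(obj.index, pd.PeriodIndex):
            raise TypeError("series must have a monthly PeriodIndex")
        years = obj.index.year.to_numpy()
        months = obj.index.month.to_numpy()
        y0, y1 = baseline if baseline is not None else (years.min(), years.max())
        in_base = (years >= y0) & (years <= y1)
        if not in_base.any():
            raise ValueError(f"baseline {y0}-{y1} does not intersect the series span")
        resid = _anomaly_detrend_core(
            obj.to_numpy(dtype=float)[:, None], months, in_base, detrend
        )[:, 0]
        anom = pd.Series(resid, index=obj.index)
        if smooth:
            anom = anom.rolling(3, center=True, min_periods=1).mean()
        anom.name = obj.name
        return anom

    if isinstance(obj, xr.DataArray):
        time = pd.DatetimeIndex(obj.time.values)
        years = time.year.to_numpy()
        months = time.month.to_numpy()
        y0, y1 = baseline if baseline is not None else (years.min(), years.max())
        in_base = (years >= y0) & (years <= y1)
        if not in_base.any():
            raise ValueError(f"baseline {y0}-{y1} does not intersect the field span")
        shape = obj.shape
        resid = _anomaly_detrend_core(
            obj.values.reshape(shape[0], -1).astype(float), months, in_base, detrend
        ).reshape(shape)
        anom = xr.DataArray(resid, coords=obj.coords, dims=obj.dims, name=obj.name)
        if smooth:
            anom = anom.rolling(time=3, center=True, min_periods=1).mean()
        anom.attrs.update(obj.attrs)
        return anom

    raise TypeError(f"cannot preprocess object of type {type(obj)!r}")


def regrid_like(field: xr.DataArray, target: xr.DataArray) -> xr.DataArray:
    """Bilinear interpolation of a field onto another field's lat/lon grid.

    Used to bring differently resolved fields onto a common grid before
    masking or differencing; extrapolation outside the source grid is
    not attempted (NaNs are returned there).
    """
    return field.interp(lat=target.lat, lon=target.lon, method="linear")


def regional_mean(field: xr.DataArray, mask: xr.DataArray) -> pd.Series:
    """Cos-latitude-weighted mean over masked grid cells, per month.

    ``mask`` is a boolean (lat, lon) array selecting e.g. the plantation
    cells of a region; sub-regions are just different masks.
    """
    mask = mask.astype(bool)
    if not bool(mask.any()):
        raise ValueError("mask selects no grid cells")
    w2d = xr.ones_like(field.isel(time=0), dtype=float) * xr.DataArray(
        _coslat_weights(field.lat), coords={"lat": field.lat}, dims="lat"
    )
    w2d = w2d.where(mask, 0.0)
    mean = field.weighted(w2d).mean(dim=("lat", "lon"))
    idx = pd.DatetimeIndex(mean.time.values).to_period("M")
    return pd.Series(mean.values, index=idx)
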