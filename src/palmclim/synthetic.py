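"""Synthetic monthly climate fields, indices and yields with known structure.

Everything the analysis pipeline consumes can be generated here with a
controlled statistical skeleton, so each downstream stage is testable
without any data downloads:

* an **ENSO-like driver**: a monthly AR(1) process whose innovation
  variance is multiplicatively phase-locked to boreal winter, mimicking
  the observed ENSO life cycle (onset in summer, peak in winter);
* **monthly fields** on a small "land" grid (precipitation, max/min/mean
  2 m temperature, dew point, net solar radiation, 10 m wind, surface
  pressure), each built as a truncated-Fourier seasonal climatology plus
  a per-variable teleconnection loading on the driver plus spatially
  correlated (isotropic exponential) Gaussian noise;
* an **SST domain** carrying an equatorial-Pacific pattern proportional
  to the driver, from which Niño3/Ningaloo/Modoki-style/dipole box
  indices are computed;
* **850 hPa winds** on a wider grid for the monsoon index;
* **annual yields** produced by a known linear model: a polynomial
  trend plus declared coefficients on lagged regional-mean predictors
  plus Gaussian noise, with the generating coefficients and implied
  low/high-year labels returned as ground truth for recovery tests.

Identical seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .derived import box_sst_index, monsoon_index, regional_mean
from .lags import predictor_at_calendar

__all__ = [
    "GridSpec",
    "EnsoConfig",
    "YieldTerm",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_pressure_level_stack",
    "seasonal_climatology",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular lat-lon grid given by extents (inclusive) and resolution."""

    lat: tuple[float, float]
    lon: tuple[float, float]
    resolution: float

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError(f"grid resolution must be positive, got {self.resolution}")
        if self.lat[1] < self.lat[0] or self.lon[1] < self.lon[0]:
            raise ValueError("grid extents must be (min, max)")

    @property
    def lats(self) -> np.ndarray:
        return np.arange(self.lat[0], self.lat[1] + 1e-9, self.resolution)

    @property
    def lons(self) -> np.ndarray:
        return np.arange(self.lon[0], self.lon[1] + 1e-9, self.resolution)


@dataclass(frozen=True)
class EnsoConfig:
    """AR(1) driver parameters: stationary SD, persistence, winter locking."""

    amplitude: float = 1.0
    ar1: float = 0.85
    phase_locking: float = 0.4


@dataclass(frozen=True)
class YieldTerm:
    """One term of the generating yield model: coefficient on a lagged predictor."""

    variable: str
    month: int
    year_offset: int
    coefficient: float


# seasonal climatology parameters per variable:
# (mean, annual amplitude, annual phase month, semiannual amplitude, semiannual phase)
_CLIM = {
    "PRCP": (200.0, 60.0, 11.0, 25.0, 4.0),   # mm month-1, NE-monsoon wet peak
    "TX2M": (31.0, 0.8, 5.0, 0.3, 2.0),       # deg C
    "TN2M": (23.0, 0.5, 5.0, 0.2, 2.0),       # deg C
    "T2M": (27.0, 0.6, 5.0, 0.2, 2.0),        # deg C
    "D2M": (23.5, 0.4, 5.0, 0.2, 2.0),        # deg C
    "SSR": (17.0, 1.5, 3.0, 0.8, 8.0),        # MJ m-2 d-1
    "W10": (3.0, 0.8, 1.0, 0.3, 7.0),         # m s-1
    "SP": (101000.0, 150.0, 1.0, 50.0, 7.0),  # Pa
    "SST": (27.0, 1.0, 3.0, 0.3, 1.0),        # deg C (plus latitude gradient)
    "U850": (0.0, 4.0, 1.0, 1.0, 4.0),        # m s-1, reversing monsoon flow
    "V850": (0.0, 3.0, 7.0, 1.0, 2.0),        # m s-1
}

LAND_VARIABLES = ("PRCP", "TX2M", "TN2M", "T2M", "D2M", "SSR", "W10", "SP")


def _default_teleconnection() -> dict[str, float]:
    # regression weight of each field onto a unit-SD driver; signs follow
    # the canonical El Nino response over the Maritime Continent
    return {
        "PRCP": -35.0, "TX2M": 0.35, "TN2M": 0.30, "T2M": 0.30, "D2M": -0.10,
        "SSR": 0.70, "W10": 0.0, "SP": 0.0, "U850": 1.5, "V850": -0.8,
    }


def _default_noise_sd() -> dict[str, float]:
    return {
        "PRCP": 30.0, "TX2M": 0.35, "TN2M": 0.30, "T2M": 0.30, "D2M": 0.35,
        "SSR": 0.9, "W10": 0.4, "SP": 80.0, "SST": 0.35, "U850": 1.2, "V850": 1.2,
    }


def _default_yield_terms() -> list[YieldTerm]:
    # shape of the Malaysia-wide two-stage model: one precipitation lag
    # from the year before harvest plus two remote SST-index terms
    return [
        YieldTerm("PRCP", 7, -1, 0.0158),
        YieldTerm("NINO3", 3, 0, -0.678),
        YieldTerm("NNI", 7, 0, -0.999),
    ]


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic dataset."""

    n_years: int = 28
    start_year: int = 1987
    spinup_years: int = 3
    land_grid: GridSpec = field(
        default_factory=lambda: GridSpec((0.5, 7.5), (99.5, 119.5), 1.0)
    )
    wind_grid: GridSpec = field(
        default_factory=lambda: GridSpec((0.0, 15.0), (80.0, 125.0), 2.5)
    )
    sst_grid: GridSpec = field(
        default_factory=lambda: GridSpec((-30.0, 30.0), (40.0, 290.0), 5.0)
    )
    mask_fraction: float = 0.6
    enso: EnsoConfig = field(default_factory=EnsoConfig)
    teleconnection: dict[str, float] = field(default_factory=_default_teleconnection)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    noise_length_scale: float = 8.0  # e-folding distance of spatial noise, degrees
    sst_pattern_amplitude: float = 1.1  # peak deg C per unit driver
    yield_terms: list[YieldTerm] = field(default_factory=_default_yield_terms)
    yield_intercept: float = 18.0
    yield_noise_sd: float = 0.35
    trend: tuple[float, ...] = (0.0, 0.03)  # Mg ha-1 polynomial in (year - start)
    seed: int = 0

    def validate(self) -> None:
        if self.n_years < 10:
            raise ValueError(f"n_years must be >= 10, got {self.n_years}")
        if not 0 < self.mask_fraction <= 1:
            raise ValueError(f"mask_fraction must be in (0, 1], got {self.mask_fraction}")
        if self.yield_noise_sd < 0 or any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")
        if self.noise_length_scale <= 0:
            raise ValueError("noise_length_scale must be positive")
        if self.spinup_years < 3:
            raise ValueError("need >= 3 spinup years for 48-month composite windows")

    @property
    def n_months(self) -> int:
        return (self.n_years + self.spinup_years) * 12

    @property
    def time(self) -> pd.DatetimeIndex:
        return pd.date_range(
            start=f"{self.start_year - self.spinup_years}-01-01",
            periods=self.n_months, freq="MS",
        )

    @property
    def harvest_years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a generated dataset."""

    enso_index: pd.Series
    true_intercept: float
    true_coefficients: dict[str, float]  # per YieldTerm label
    true_trend: tuple[float, ...]
    true_labels: np.ndarray  # low/normal/high per harvest year


@dataclass
class SyntheticDataset:
    """A complete generated input set for the analysis pipeline."""

    config: SyntheticConfig
    fields: dict[str, xr.DataArray]
    sst: xr.DataArray
    u850: xr.DataArray
    v850: xr.DataArray
    mask: xr.DataArray
    indices: dict[str, pd.Series]
    yields: pd.Series
    truth: SyntheticTruth


def seasonal_climatology(variable: str, months: np.ndarray, lats=None) -> np.ndarray:
    """Truncated-Fourier (annual + semiannual) climatology of one variable.

    ``months`` are calendar months 1..12; for SST a meridional gradient
    is added and the result has shape (time, lat) when ``lats`` given.
    """
    mean, a1, p1, a2, p2 = _CLIM[variable]
    m = np.asarray(months, dtype=float)
    out = (
        mean
        + a1 * np.cos(2 * np.pi * (m - p1) / 12.0)
        + a2 * np.cos(4 * np.pi * (m - p2) / 12.0)
    )
    if variable == "SST" and lats is not None:
        grad = -10.0 * (np.asarray(lats, dtype=float) / 30.0) ** 2
        out = out[:, None] + grad[None, :]
    return out


def _spatial_noise_chol(grid: GridSpec, length_scale: float) -> np.ndarray:
    """Cholesky factor of an isotropic exponential spatial covariance."""
    la, lo = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    pts = np.column_stack([la.ravel(), lo.ravel()])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1))
    cov = np.exp(-d / length_scale)
    # tiny jitter keeps the factorization stable for dense grids
    return np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))


def _enso_driver(config: SyntheticConfig, rng) -> np.ndarray:
    """Monthly AR(1) driver with winter-phase-locked innovation variance."""
    e = config.enso
    months = config.time.month.to_numpy()
    # innovation SD largest around January (boreal winter peak)
    s = 1.0 + e.phase_locking * np.cos(2 * np.pi * (months - 1) / 12.0)
    eps = rng.standard_normal(config.n_months)
    x = np.empty(config.n_months)
    x[0] = s[0] * eps[0] / np.sqrt(1.0 - e.ar1**2)
    for t in range(1, config.n_months):
        x[t] = e.ar1 * x[t - 1] + s[t] * eps[t]
    # rescale to the configured stationary amplitude (deterministic factor)
    scale = np.sqrt(np.mean(s**2) / (1.0 - e.ar1**2))
    return e.amplitude * x / scale


def _field(config, grid, variable, enso, chol, rng, pattern=None) -> xr.DataArray:
    months = config.time.month.to_numpy()
    lats, lons = grid.lats, grid.lons
    n_cells = len(lats) * len(lons)
    clim = seasonal_climatology(variable, months, lats if variable == "SST" else None)
    vals = np.empty((config.n_months, len(lats), len(lons)))
    if variable == "SST":
        vals[:] = clim[:, :, None]
    else:
        vals[:] = clim[:, None, None]
    if pattern is not None:
        vals += enso[:, None, None] * pattern[None, :, :]
    else:
        w = config.teleconnection.get(variable, 0.0)
        vals += w * enso[:, None, None]
    sd = config.noise_sd.get(variable, 0.0)
    if sd > 0:
        z = rng.standard_normal((n_cells, config.n_months))
        noise = (chol @ z).T.reshape(config.n_months, len(lats), len(lons))
        vals += sd * noise
    units = {
        "PRCP": "mm month-1", "TX2M": "degC", "TN2M": "degC", "T2M": "degC",
        "D2M": "degC", "SSR": "MJ m-2 d-1", "W10": "m s-1", "SP": "Pa",
        "SST": "degC", "U850": "m s-1", "V850": "m s-1",
    }[variable]
    return xr.DataArray(
        vals,
        coords={"time": config.time, "lat": lats, "lon": lons},
        dims=("time", "lat", "lon"),
        name=variable,
        attrs={"units": units},
    )


def _sst_pattern(grid: GridSpec, amplitude: float) -> np.ndarray:
    """Equatorial-Pacific loading of SST on the driver (El Nino-like)."""
    la, lo = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    return amplitude * np.exp(-((la / 12.0) ** 2)) * np.exp(-(((lo - 235.0) / 45.0) ** 2))


def _anomaly(field_da: xr.DataArray, variable: str) -> xr.DataArray:
    """Subtract the generator's own (known) climatology."""
    months = pd.DatetimeIndex(field_da.time.values).month.to_numpy()
    clim = seasonal_climatology(
        variable, months, field_da.lat.values if variable == "SST" else None
    )
    if variable == "SST":
        return field_da - clim[:, :, None]
    return field_da - clim[:, None, None]


# index boxes on the synthetic SST domain (lat range, lon range)
INDEX_BOXES = {
    "NINO3": ((-5.0, 5.0), (210.0, 270.0)),
    "NNI": ((-28.0, -22.0), (108.0, 116.0)),
    "MODOKI": ((-10.0, 10.0), (165.0, 220.0)),
    "DMI_WEST": ((-10.0, 10.0), (50.0, 70.0)),
    "DMI_EAST": ((-10.0, 0.0), (90.0, 110.0)),
}


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate one complete synthetic dataset from a config.

    Deterministic in ``config.seed``.  See the module docstring for the
    generating structure; the returned ``indices`` are anomalies with
    respect to the generator's true climatology, and the yields are an
    exact linear function of those index series (plus trend and noise),
    so coefficient-recovery tests can use them directly.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    enso = _enso_driver(config, rng)
    chol_land = _spatial_noise_chol(config.land_grid, config.noise_length_scale)
    chol_wind = _spatial_noise_chol(config.wind_grid, config.noise_length_scale)
    chol_sst = _spatial_noise_chol(config.sst_grid, config.noise_length_scale)

    fields = {
        v: _field(config, config.land_grid, v, enso, chol_land, rng)
        for v in LAND_VARIABLES
    }
    sst = _field(
        config, config.sst_grid, "SST", enso, chol_sst, rng,
        pattern=_sst_pattern(config.sst_grid, config.sst_pattern_amplitude),
    )
    u850 = _field(config, config.wind_grid, "U850", enso, chol_wind, rng)
    v850 = _field(config, config.wind_grid, "V850", enso, chol_wind, rng)

    # plantation mask on the land grid
    n_lat, n_lon = len(config.land_grid.lats), len(config.land_grid.lons)
    n_cells = n_lat * n_lon
    n_masked = max(1, int(round(config.mask_fraction * n_cells)))
    flat = np.zeros(n_cells, dtype=bool)
    flat[rng.choice(n_cells, size=n_masked, replace=False)] = True
    mask = xr.DataArray(
        flat.reshape(n_lat, n_lon),
        coords={"lat": config.land_grid.lats, "lon": config.land_grid.lons},
        dims=("lat", "lon"),
        name="plantation_mask",
    )

    sst_anom = _anomaly(sst, "SST")
    indices: dict[str, pd.Series] = {}
    for name in ("NINO3", "NNI", "MODOKI"):
        indices[name] = box_sst_index(sst_anom, *INDEX_BOXES[name], name=name)
    dmi = box_sst_index(
        sst_anom, *INDEX_BOXES["DMI_WEST"], name="DMI"
    ) - box_sst_index(sst_anom, *INDEX_BOXES["DMI_EAST"], name="DMI")
    dmi.name = "DMI"
    indices["DMI"] = dmi
    icmi = monsoon_index(_anomaly(u850, "U850"), _anomaly(v850, "V850"))
    indices["ICMI"] = icmi
    for v in LAND_VARIABLES:
        series = regional_mean(_anomaly(fields[v], v), mask)
        series.name = v
        indices[v] = series

    years = config.harvest_years
    offsets = np.asarray(years - config.start_year, dtype=float)
    trend = np.polynomial.polynomial.polyval(offsets, np.asarray(config.trend))
    y = np.full(config.n_years, config.yield_intercept, dtype=float) + trend
    coeffs: dict[str, float] = {}
    for term in config.yield_terms:
        vals = predictor_at_calendar(
            indices[term.variable], years, term.month, term.year_offset
        )
        y += term.coefficient * vals
        mon = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"][term.month - 1]
        coeffs[f"{term.variable}_{mon}{term.year_offset:+d}".replace("+0", "0")] = (
            term.coefficient
        )
    if config.yield_noise_sd > 0:
        y += config.yield_noise_sd * rng.standard_normal(config.n_years)
    yields = pd.Series(y, index=pd.Index(years, name="year"), name="yield")

    truth = SyntheticTruth(
        enso_index=pd.Series(enso, index=config.time.to_period("M"), name="ENSO"),
        true_intercept=config.yield_intercept,
        true_coefficients=coeffs,
        true_trend=tuple(config.trend),
        true_labels=_truth_labels(y),
    )
    return SyntheticDataset(
        config=config, fields=fields, sst=sst, u850=u850, v850=v850,
        mask=mask, indices=indices, yields=yields, truth=truth,
    )


def _truth_labels(y: np.ndarray, span: float = 0.32, k: float = 0.7) -> np.ndarray:
    """Low/normal/high labels implied by the generated yields.

    Deliberately computed with the reference lowess smoother from
    statsmodels (locally linear, tricube weights, no robustness
    iterations) rather than the package's own loess, so that agreement
    between truth labels and pipeline labels is a genuine cross-check of
    two independent smoother implementations.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.arange(len(y), dtype=float)
    trend = lowess(y, x, frac=span, it=0, return_sorted=False)
    rate = 100.0 * (y - trend) / trend
    thr = k * np.std(rate, ddof=1)
    labels = np.full(len(y), "normal", dtype=object)
    labels[rate < -thr] = "low"
    labels[rate > thr] = "high"
    return labels.astype(str)


def generate_pressure_level_stack(
    config: SyntheticConfig | None = None,
    surface_pressure: xr.DataArray | None = None,
    n_levels: int = 21,
    p_top: float = 25000.0,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Columns of specific humidity and wind on pressure levels.

    Levels run linearly from the (per-column) surface pressure up to
    ``p_top`` (250 hPa by default, giving 21 levels / 20 layer
    differences).  Humidity falls off as (p/ps)^3 from a surface value;
    winds have a linear shear plus noise.  Exists purely to exercise the
    vertically integrated moisture-flux computation.

    Returns arrays keyed ``q``, ``u``, ``v``, ``pressures``, each with
    the level axis first followed by the surface-pressure dims.
    """
    if n_levels < 2:
        raise ValueError(f"need at least 2 pressure levels, got {n_levels}")
    if config is None:
        config = SyntheticConfig()
    if surface_pressure is None:
        rng0 = np.random.default_rng(config.seed if seed is None else seed)
        ps = 101000.0 + 300.0 * rng0.standard_normal((4, 3, 3))
    else:
        ps = np.asarray(surface_pressure.values, dtype=float)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    frac = np.linspace(0.0, 1.0, n_levels)  # 0 at surface, 1 at top
    shape = (n_levels,) + ps.shape
    pressures = ps[None, ...] + frac.reshape((-1,) + (1,) * ps.ndim) * (p_top - ps[None, ...])
    rel = pressures / ps[None, ...]
    q = 0.016 * rel**3
    u = 2.0 + 10.0 * (1.0 - rel) + 0.5 * rng.standard_normal(shape)
    v = -1.0 + 4.0 * (1.0 - rel) + 0.5 * rng.standard_normal(shape)
    return {"q": q, "u": u, "v": v, "pressures": pressures}
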