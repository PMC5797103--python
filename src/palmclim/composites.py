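"""Composite analysis of low- vs high-yield years with permutation tests.

Two modes mirror the two kinds of composite the analysis draws:

* **time-series composites** — for a regional-mean monthly variable, the
  mean over low-yield years and over high-yield years of each of the 48
  months from January three years before harvest (Jan_-3) to December of
  the harvest year (Dec_0), expressed as deviations from the all-years
  mean for that relative month, with standard errors and a two-sided
  permutation t-test per month;

* **map composites** — for a gridded anomaly field, seasonal (SON_-1,
  DJF, MAM, JJA) group-mean maps with per-cell permutation significance:
  Student's t for scalar fields, the two-sample Hotelling T² statistic
  for 2-component vector fields (moisture flux).

The permutation null reassigns group labels at random among the union
of low and high years only (normal years never enter the contrast), and
p-values use the (b+1)/(B+1) estimator so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .variability import YieldRecord

__all__ = [
    "CompositeResult",
    "StressWindow",
    "STRESS_WINDOWS",
    "composite_timeseries",
    "composite_maps",
    "hotelling_t2",
    "window_months",
]

WINDOW = 48  # months: Jan three years before harvest through Dec of harvest

# order in the standard seasonal composite: boreal fall of the previous
# year, then winter spanning the year boundary, spring and summer of the
# harvest year
SEASONS = {
    "SON-1": [(9, -1), (10, -1), (11, -1)],
    "DJF": [(12, -1), (1, 0), (2, 0)],
    "MAM": [(3, 0), (4, 0), (5, 0)],
    "JJA": [(6, 0), (7, 0), (8, 0)],
}


@dataclass(frozen=True)
class StressWindow:
    """A physiologically stress-sensitive window before harvest.

    ``months_before_harvest`` counts back from the September–October
    harvest peak; used only to annotate composite plots/tables.
    """

    name: str
    months_before_harvest: tuple[int, int]


STRESS_WINDOWS = (
    StressWindow("sex determination", (31, 20)),
    StressWindow("inflorescence abortion", (12, 8)),
    StressWindow("bunch failure", (4, 2)),
)


@dataclass
class CompositeResult:
    """Group means (as deviations), SEs and permutation p-values."""

    axis: np.ndarray  # month labels or flattened grid/season shape info
    mean_low: np.ndarray
    mean_high: np.ndarray
    se_low: np.ndarray
    se_high: np.ndarray
    pvalue: np.ndarray
    n_low: int
    n_high: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": self.axis,
                "mean_low": np.ravel(self.mean_low),
                "mean_high": np.ravel(self.mean_high),
                "se_low": np.ravel(self.se_low),
                "se_high": np.ravel(self.se_high),
                "pvalue": np.ravel(self.pvalue),
            }
        )


def window_months(year: int) -> pd.PeriodIndex:
    """The 48 monthly periods Jan(year-3) .. Dec(year)."""
    return pd.period_range(start=f"{year - 3}-01", periods=WINDOW, freq="M")


def month_axis_labels() -> np.ndarray:
    names = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
             "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
    return np.array([f"{names[m]}{-3 + y}" for y in range(4) for m in range(12)])


def _t_stat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t along axis 0; vectorized over trailing dims."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.where(np.isfinite(t), t, 0.0)


def _perm_pvalues_t(pooled, is_low, n_perm, rng, joint=False):
    """Permutation p for |t| with labels resampled over the pooled years.

    ``pooled`` is a (years, points) array in canonical (year) order and
    ``is_low`` the boolean group mask over its rows; normal years never
    enter.  Each permutation draw reassigns a subset of size
    min(n_low, n_high) — |t| only depends on the unordered partition, so
    p-values are exactly invariant under swapping the low/high labels.
    With ``joint=False`` (the default) the pooled sample is shuffled
    independently at each point; with ``joint=True`` one year-relabelling
    is shared by all points of a permutation draw.
    """
    low, high = pooled[is_low], pooled[~is_low]
    t_obs = np.abs(_t_stat(low, high))
    count = np.zeros_like(t_obs)
    k = min(low.shape[0], high.shape[0])
    for _ in range(n_perm):
        if joint:
            perm = pooled[rng.permutation(pooled.shape[0])]
        else:
            perm = rng.permuted(pooled, axis=0)
        t_p = np.abs(_t_stat(perm[:k], perm[k:]))
        count += t_p >= t_obs - 1e-12
    return (count + 1.0) / (n_perm + 1.0)


def composite_timeseries(
    series: pd.Series,
    record: YieldRecord,
    n_perm: int = 10000,
    seed: int | None = None,
    joint_permutation: bool = False,
) -> CompositeResult:
    """48-month composite of a regional monthly series over low/high years.

    ``series`` must be a monthly PeriodIndex series covering Jan three
    years before the first labelled harvest year through Dec of the last.
    Deviations are taken from the mean over *all* study years at each
    relative month, so low and high curves share a common reference.
    """
    rng = np.random.default_rng(seed)
    mats = {}
    for y in record.years:
        months = window_months(int(y))
        missing = months.difference(series.index)
        if len(missing):
            raise ValueError(
                f"series does not cover the 48-month window of year {y}"
            )
        mats[int(y)] = series.loc[months].to_numpy(dtype=float)
    all_mat = np.array([mats[int(y)] for y in record.years])
    labelled = record.labels != "normal"
    pooled = all_mat[labelled]
    is_low = record.labels[labelled] == "low"
    low, high = pooled[is_low], pooled[~is_low]
    if low.shape[0] < 2 or high.shape[0] < 2:
        raise ValueError("need at least 2 low and 2 high years")

    ref = all_mat.mean(axis=0)
    res = CompositeResult(
        axis=month_axis_labels(),
        mean_low=low.mean(axis=0) - ref,
        mean_high=high.mean(axis=0) - ref,
        se_low=low.std(axis=0, ddof=1) / np.sqrt(low.shape[0]),
        se_high=high.std(axis=0, ddof=1) / np.sqrt(high.shape[0]),
        pvalue=_perm_pvalues_t(pooled, is_low, n_perm, rng, joint=joint_permutation),
        n_low=low.shape[0],
        n_high=high.shape[0],
    )
    return res


def hotelling_t2(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Hotelling T² with pooled covariance.

    ``a``/``b`` are (n, p) samples of p-dimensional vectors.
    """
    n1, n2 = a.shape[0], b.shape[0]
    d = a.mean(axis=0) - b.mean(axis=0)
    s1 = np.cov(a, rowvar=False, ddof=1)
    s2 = np.cov(b, rowvar=False, ddof=1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    sp = np.atleast_2d(sp)
    try:
        sol = np.linalg.solve(sp, d)
    except np.linalg.LinAlgError:
        return 0.0
    return float(n1 * n2 / (n1 + n2) * d @ sol)


def _seasonal_values(field: xr.DataArray, year: int, season: str) -> np.ndarray:
    """Mean of a field over one season relative to harvest ``year`` → (lat, lon)."""
    periods = pd.PeriodIndex(
        [pd.Period(year=year + off, month=m, freq="M") for m, off in SEASONS[season]]
    )
    idx = pd.DatetimeIndex(field.time.values).to_period("M")
    pos = [int(np.where(idx == p)[0][0]) if (idx == p).any() else -1 for p in periods]
    if any(p < 0 for p in pos):
        raise ValueError(f"season {season} of year {year} missing from field span")
    return field.isel(time=pos).mean("time").values


def composite_maps(
    field: xr.DataArray | tuple[xr.DataArray, xr.DataArray],
    record: YieldRecord,
    seasons=tuple(SEASONS),
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict[str, CompositeResult]:
    """Seasonal map composites with per-cell permutation significance.

    Pass a single anomaly DataArray for a scalar field (t statistic) or a
    ``(u, v)`` pair for a vector field (Hotelling T²).  Returns one
    :class:`CompositeResult` per season, each holding (lat, lon) arrays;
    for vector fields means/SEs are stacked as (2, lat, lon) with the
    shared T² p-value per cell.
    """
    rng = np.random.default_rng(seed)
    vector = isinstance(field, tuple)
    comps = field if vector else (field,)
    out: dict[str, CompositeResult] = {}
    for season in seasons:
        # (years, lat*lon) per component
        stacks = []
        for comp in comps:
            per_year = np.array(
                [_seasonal_values(comp, int(y), season).ravel() for y in record.years]
            )
            stacks.append(per_year)
        shape = comps[0].isel(time=0).shape
        is_low = np.isin(record.years, record.low_years)
        is_high = np.isin(record.years, record.high_years)
        if is_low.sum() < 2 or is_high.sum() < 2:
            raise ValueError("need at least 2 low and 2 high years")
        ref = [s.mean(axis=0) for s in stacks]
        mean_low = np.stack([s[is_low].mean(axis=0) - r for s, r in zip(stacks, ref)])
        mean_high = np.stack([s[is_high].mean(axis=0) - r for s, r in zip(stacks, ref)])
        se_low = np.stack(
            [s[is_low].std(axis=0, ddof=1) / np.sqrt(is_low.sum()) for s in stacks]
        )
        se_high = np.stack(
            [s[is_high].std(axis=0, ddof=1) / np.sqrt(is_high.sum()) for s in stacks]
        )
        labelled = is_low | is_high
        if vector:
            pv = _perm_pvalues_t2(stacks, is_low, is_high, n_perm, rng)
        else:
            pv = _perm_pvalues_t(
                stacks[0][labelled], is_low[labelled], n_perm, rng, joint=True
            )
        res = CompositeResult(
            axis=np.arange(stacks[0].shape[1]),
            mean_low=mean_low.reshape((len(comps),) + shape).squeeze(),
            mean_high=mean_high.reshape((len(comps),) + shape).squeeze(),
            se_low=se_low.reshape((len(comps),) + shape).squeeze(),
            se_high=se_high.reshape((len(comps),) + shape).squeeze(),
            pvalue=pv.reshape(shape),
            n_low=int(is_low.sum()),
            n_high=int(is_high.sum()),
        )
        res.significant = res.pvalue < alpha
        out[season] = res
    return out


def _perm_pvalues_t2(stacks, is_low, is_high, n_perm, rng):
    """Per-cell permutation p for the two-sample Hotelling T² statistic."""
    lab_idx = np.where(is_low | is_high)[0]
    # (years_in_contrast, cells, p), rows in canonical year order
    data = np.stack([s[lab_idx] for s in stacks], axis=-1)
    low_pos = np.isin(lab_idx, np.where(is_low)[0])
    obs = _t2_cells(data[low_pos], data[~low_pos])
    count = np.zeros_like(obs)
    n_tot = data.shape[0]
    k = min(int(low_pos.sum()), int((~low_pos).sum()))
    for _ in range(n_perm):
        perm = data[rng.permutation(n_tot)]
        count += _t2_cells(perm[:k], perm[k:]) >= obs - 1e-12
    return (count + 1.0) / (n_perm + 1.0)


def _t2_cells(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sample T² over cells; a, b are (n, cells, p)."""
    n1, n2 = a.shape[0], b.shape[0]
    d = a.mean(axis=0) - b.mean(axis=0)  # (cells, p)
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    s = (
        np.einsum("ncp,ncq->cpq", am, am) + np.einsum("ncp,ncq->cpq", bm, bm)
    ) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(s, d[..., None])[..., 0]
    except np.linalg.LinAlgError:
        sol = np.stack([np.linalg.lstsq(s[c], d[c], rcond=None)[0]
                        for c in range(s.shape[0])])
    t2 = n1 * n2 / (n1 + n2) * np.einsum("cp,cp->c", d, sol)
    return np.where(np.isfinite(t2), t2, 0.0)
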