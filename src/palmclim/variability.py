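"""Interannual yield variation rate and low/normal/high year classification.

Annual fresh-fruit-bunch yields mix a slow agronomic/management trend
(planted area, palm age structure, practices) with the interannual
climate signal of interest.  The trend is estimated by loess (locally
weighted regression: tricube kernel, nearest-neighbour bandwidth, local
degree-1 polynomials, no robustness iterations) and the variation rate
is the percent deviation of each year's yield from that trend.  Years
whose rate exceeds ±k standard deviations of the rate series (default
k = 0.7) are classified as high/low production years; the rest are
normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["YieldRecord", "loess_trend", "variation_rate", "classify_years", "build_record"]


@dataclass
class YieldRecord:
    """Annual yields of one region with derived rate and year labels."""

    region: str
    years: np.ndarray
    yields: np.ndarray
    trend: np.ndarray
    rate: np.ndarray  # percent deviation from trend
    labels: np.ndarray  # 'low' | 'normal' | 'high'
    threshold: float  # percent, k * SD of rate

    def __post_init__(self):
        d = np.diff(self.years)
        if len(d) and not np.all(d == 1):
            raise ValueError("years must be strictly increasing and contiguous")

    @property
    def low_years(self) -> np.ndarray:
        return self.years[self.labels == "low"]

    @property
    def high_years(self) -> np.ndarray:
        return self.years[self.labels == "high"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "yield": self.yields,
                "trend": self.trend,
                "rate": self.rate,
                "label": self.labels,
            }
        )


def loess_trend(y: np.ndarray, span: float = 0.32, degree: int = 1) -> np.ndarray:
    """Loess smooth of a series against its own integer time axis.

    Classic locally weighted regression: at each point the
    ``k = int(span * n)`` nearest neighbours (the truncation rule of the
    classic reference implementations) get tricube weights scaled by the
    distance to the k-th neighbour, and a weighted polynomial of the
    given degree is fitted and evaluated at the point.  No robustness
    iterations.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    k = min(n, int(span * n + 1e-9))
    if k < degree + 1:
        raise ValueError(
            f"span {span} gives {k} points per window; need at least {degree + 1}"
        )
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h == 0:  # all neighbours coincide; degenerate but defined
            out[i] = y[idx].mean()
            continue
        w = (1.0 - np.clip(d[idx] / h, 0.0, 1.0) ** 3) ** 3
        X = np.vander(x[idx] - x[i], degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def variation_rate(
    yields: pd.Series | np.ndarray, span: float = 0.32, degree: int = 1
) -> np.ndarray:
    """Percent deviation of annual yields from their loess trend.

    rate(t) = 100 * (yield(t) - trend(t)) / trend(t).  Scale-free:
    multiplying the whole series by a positive constant leaves the rate
    unchanged.
    """
    y = np.asarray(yields, dtype=float)
    if len(y) < 8:
        raise ValueError("need at least 8 years of yields")
    trend = loess_trend(y, span=span, degree=degree)
    if np.any(trend == 0):
        raise ValueError("loess trend crosses zero; percent rate undefined")
    return 100.0 * (y - trend) / trend


def classify_years(
    rate: np.ndarray, k: float = 0.7, ddof: int = 1
) -> tuple[np.ndarray, float]:
    """Label each year low/normal/high against a ±k·SD rate threshold.

    Returns ``(labels, threshold)`` where threshold = k * sample SD of
    the rate (ddof=1 by default).
    """
    rate = np.asarray(rate, dtype=float)
    sd = float(np.std(rate, ddof=ddof))
    if sd == 0:
        raise ValueError("rate series has zero variance; classification undefined")
    threshold = k * sd
    labels = np.full(len(rate), "normal", dtype=object)
    labels[rate < -threshold] = "low"
    labels[rate > threshold] = "high"
    return labels.astype(str), threshold


def build_record(
    region: str,
    yields: pd.Series,
    span: float = 0.32,
    degree: int = 1,
    k: float = 0.7,
) -> YieldRecord:
    """Full pipeline: loess trend → variation rate → year labels."""
    years = np.asarray(yields.index, dtype=int)
    y = yields.to_numpy(dtype=float)
    trend = loess_trend(y, span=span, degree=degree)
    rate = 100.0 * (y - trend) / trend
    labels, threshold = classify_years(rate, k=k)
    return YieldRecord(
        region=region, years=years, yields=y, trend=trend,
        rate=rate, labels=labels, threshold=threshold,
    )
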