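"""Month-lag bookkeeping between annual harvests and monthly predictors.

A lag of ``l`` months counts back from December of the harvest year, so
lag 0 is Dec of the harvest year, lag 9 is March of the harvest year
(Mar_0), lag 17 is July of the previous year (Jul_-1), and lag 30 is
June two years before (Jun_-2).  Every module that pairs annual yields
with monthly series goes through these helpers so the convention lives
in exactly one place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "lag_to_calendar",
    "calendar_to_lag",
    "predictor_at_lag",
    "predictor_at_calendar",
]


def lag_to_calendar(lag: int) -> tuple[int, int]:
    """Convert a month lag to a (calendar month, year offset) pair.

    Parameters
    ----------
    lag : int
        Months by which the predictor leads December of the harvest year.

    Returns
    -------
    (month, year_offset)
        ``month`` in 1..12, ``year_offset`` 0 for the harvest year,
        -1 for the year before, etc.
    """
    if lag < 0:
        raise ValueError(f"lag must be non-negative, got {lag}")
    total = 12 - lag  # month number counted from January of the harvest year
    year_offset = (total - 1) // 12
    month = (total - 1) % 12 + 1
    return month, year_offset


def calendar_to_lag(month: int, year_offset: int) -> int:
    """Inverse of :func:`lag_to_calendar`."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return 12 - (year_offset * 12 + month)


def predictor_at_calendar(
    series: pd.Series, years: np.ndarray, month: int, year_offset: int
) -> np.ndarray:
    """Sample a monthly series at a fixed calendar month relative to each year.

    ``series`` must be indexed by a monthly :class:`pandas.PeriodIndex`.
    Missing months raise ``KeyError`` — silent gaps would corrupt the
    pairing of predictors with harvest years.
    """
    if not isinstance(series.index, pd.PeriodIndex):
        raise TypeError("monthly series must have a PeriodIndex (freq='M')")
    periods = pd.PeriodIndex(
        [pd.Period(year=int(y) + year_offset, month=month, freq="M") for y in years]
    )
    missing = periods.difference(series.index)
    if len(missing):
        raise KeyError(f"series does not cover required months: {list(missing[:4])}")
    return series.loc[periods].to_numpy(dtype=float)


def predictor_at_lag(series: pd.Series, years: np.ndarray, lag: int) -> np.ndarray:
    """Sample a monthly series ``lag`` months before December of each year."""
    month, year_offset = lag_to_calendar(lag)
    return predictor_at_calendar(series, years, month, year_offset)
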