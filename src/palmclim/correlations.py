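"""Lagged and partial lagged correlations with random-phase significance.

Annual yield variability is correlated with monthly climate predictors
at leads of 0–30 months, where lag ``l`` pairs each harvest year with
the predictor value ``l`` months before December of that year (see
:mod:`palmclim.lags`).  Because both yields and climate indices are
autocorrelated, significance comes from phase-randomized surrogates:
random series sharing the power spectrum of the predictor but with
uniformly random Fourier phases, which preserve the autocorrelation
structure under the null of no relationship.

Partial correlations isolate the contribution of one climate mode (e.g.
the Ningaloo index or the monsoon index) with ENSO held fixed.  They
are computed by precision-matrix inversion: with R the correlation
matrix of (yield, target, conditioning...) and P = R^-1, the partial
correlation of the first two given the rest is -P12 / sqrt(P11 P22).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lags import predictor_at_lag

__all__ = [
    "LagCorrelationResult",
    "lagged_correlation",
    "partial_lagged_correlation",
    "partial_correlation_matrix",
    "phase_randomize",
    "random_phase_pvalue",
]


@dataclass
class LagCorrelationResult:
    """Per-lag correlations of a predictor with annual yields."""

    predictor: str
    lags: np.ndarray
    r: np.ndarray
    p: np.ndarray
    n: int
    partial: bool = False
    conditioning: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictor,
                "lag": self.lags,
                "r": self.r,
                "p": self.p,
                "n": self.n,
                "conditioning": ",".join(self.conditioning),
            }
        )

    def significant_at(self, level: float = 0.95) -> np.ndarray:
        """Boolean mask of lags significant at the given confidence level.

        The stored p is directional (tail chosen by the sign of the
        observed correlation), so under the null it rejects at twice the
        tail probability; a correct test at ``level`` therefore compares
        it with (1 - level) / 2.
        """
        return self.p < (1.0 - level) / 2.0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("constant series has no defined correlation")
    return float(a @ b / denom)


def phase_randomize(x: np.ndarray, n_surrogates: int, rng) -> np.ndarray:
    """Surrogate series with the same power spectrum, random phases.

    The DC component is untouched (the mean is preserved exactly) and
    the Nyquist component, when present, is kept real by flipping its
    sign at random; all other Fourier coefficients keep their amplitude
    and get i.i.d. uniform phases with conjugate symmetry.  Returns an
    ``(n_surrogates, len(x))`` array.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 samples for phase randomization")
    if np.ptp(x) == 0:
        raise ValueError("constant series cannot be phase-randomized")
    spec = np.fft.rfft(x)
    n_freq = len(spec)
    amps = np.abs(spec)
    has_nyquist = n % 2 == 0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, n_freq))
    phases[:, 0] = np.angle(spec[0])  # DC: keep (real) sign
    sur_spec = amps * np.exp(1j * phases)
    sur_spec[:, 0] = spec[0]
    if has_nyquist:
        signs = rng.choice([-1.0, 1.0], size=n_surrogates)
        sur_spec[:, -1] = spec[-1].real * signs
    return np.fft.irfft(sur_spec, n=n, axis=1)


def random_phase_pvalue(
    x: pd.Series | np.ndarray,
    y: np.ndarray,
    sample_idx: np.ndarray | None = None,
    n_surrogates: int = 10000,
    seed: int | None = None,
    rng=None,
    two_sided: bool = False,
) -> tuple[float, float]:
    """Random-phase significance of the correlation between x and y.

    ``x`` is the (typically monthly, autocorrelated) series that gets
    phase-randomized; ``y`` is held fixed.  If ``sample_idx`` is given,
    x is subsampled at those positions before correlating — this is how
    a monthly predictor is paired with annual yields at a lag while the
    surrogates are built from the full monthly record.

    Returns ``(r_observed, p)``.  The default p is one-sided in the
    direction of the observed correlation: the proportion of surrogate
    correlations at least as large (observed r > 0) or at least as small
    (observed r < 0), with the observed value counted in the null set.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    xv = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if sample_idx is None:
        sample_idx = np.arange(len(y))
    r_obs = _pearson(xv[sample_idx], y)
    sur = phase_randomize(xv, n_surrogates, rng)[:, sample_idx]
    sur = sur - sur.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    norms = np.sqrt(np.einsum("ij,ij->i", sur, sur) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_sur = sur @ yc / norms
    r_sur = r_sur[np.isfinite(r_sur)]
    b = len(r_sur)
    if two_sided:
        count = np.sum(np.abs(r_sur) >= abs(r_obs))
    elif r_obs >= 0:
        count = np.sum(r_sur >= r_obs)
    else:
        count = np.sum(r_sur <= r_obs)
    return r_obs, float((count + 1.0) / (b + 1.0))


def _positions_in(series: pd.Series, years: np.ndarray, lag: int) -> np.ndarray:
    """Integer positions of the lagged months within a monthly series."""
    from .lags import lag_to_calendar

    month, off = lag_to_calendar(lag)
    periods = pd.PeriodIndex(
        [pd.Period(year=int(y) + off, month=month, freq="M") for y in years]
    )
    locs = series.index.get_indexer(periods)
    if np.any(locs < 0):
        raise ValueError(f"predictor series does not cover lag {lag}")
    return locs


def lagged_correlation(
    yield_rate: pd.Series,
    predictor: pd.Series,
    max_lag: int = 30,
    n_surrogates: int = 10000,
    seed: int | None = None,
) -> LagCorrelationResult:
    """Pearson correlation of annual yields with a monthly predictor at each lag.

    ``yield_rate`` is indexed by harvest year; ``predictor`` by monthly
    period (already preprocessed: anomaly, detrended, 3-month smoothed).
    Significance per lag comes from phase-randomized surrogates of the
    predictor, one-sided in the direction of the observed correlation.
    """
    years = np.asarray(yield_rate.index, dtype=int)
    if len(years) < 5:
        raise ValueError("need at least 5 overlapping years")
    y = yield_rate.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    lags = np.arange(max_lag + 1)
    r = np.empty(len(lags))
    p = np.empty(len(lags))
    for i, lag in enumerate(lags):
        idx = _positions_in(predictor, years, int(lag))
        r[i], p[i] = random_phase_pvalue(
            predictor.to_numpy(dtype=float), y, idx,
            n_surrogates=n_surrogates, rng=rng,
        )
    return LagCorrelationResult(
        predictor=str(predictor.name), lags=lags, r=r, p=p, n=len(years)
    )


def partial_correlation_matrix(data: np.ndarray) -> float:
    """Partial correlation of columns 0 and 1 given the rest, by inversion.

    Builds the correlation matrix of the columns, inverts it, and
    returns the negative standardized off-diagonal of the precision
    matrix: -P01 / sqrt(P00 * P11).
    """
    R = np.corrcoef(data, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("constant column in partial-correlation input")
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        pair = _most_collinear_pair(R)
        raise ValueError(
            f"singular correlation matrix; columns {pair} are collinear"
        ) from err
    cond = np.linalg.cond(R)
    if cond > 1e12:
        pair = _most_collinear_pair(R)
        raise ValueError(
            f"near-singular correlation matrix (cond={cond:.2e}); "
            f"columns {pair} are collinear"
        )
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def _most_collinear_pair(R: np.ndarray) -> tuple[int, int]:
    A = np.abs(R - np.eye(len(R)))
    i, j = np.unravel_index(np.argmax(A), A.shape)
    return (int(min(i, j)), int(max(i, j)))


def partial_lagged_correlation(
    yield_rate: pd.Series,
    target: pd.Series,
    conditioning: dict[str, pd.Series],
    max_lag: int = 30,
    n_surrogates: int = 10000,
    seed: int | None = None,
) -> LagCorrelationResult:
    """Lagged correlation of yields with ``target``, conditioning removed.

    At each lag every series (target and conditioning, all monthly) is
    sampled at the same lagged month; the partial correlation is then
    read off the inverted correlation matrix.  With an empty
    conditioning set this reduces exactly to :func:`lagged_correlation`.
    Significance: the target series is phase-randomized while yields and
    conditioning series stay fixed, and the partial correlation is
    recomputed for each surrogate.
    """
    if not conditioning:
        res = lagged_correlation(
            yield_rate, target, max_lag=max_lag,
            n_surrogates=n_surrogates, seed=seed,
        )
        res.partial = True
        return res
    if any(s is target or s.equals(target) for s in conditioning.values()):
        raise ValueError("target series also appears in the conditioning set")
    years = np.asarray(yield_rate.index, dtype=int)
    if len(years) < 5:
        raise ValueError("need at least 5 overlapping years")
    y = yield_rate.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    lags = np.arange(max_lag + 1)
    r = np.empty(len(lags))
    p = np.empty(len(lags))
    tvals = target.to_numpy(dtype=float)
    for i, lag in enumerate(lags):
        idx = _positions_in(target, years, int(lag))
        cond_cols = [
            predictor_at_lag(s, years, int(lag)) for s in conditioning.values()
        ]
        data = np.column_stack([y, tvals[idx]] + cond_cols)
        r[i] = partial_correlation_matrix(data)
        sur = phase_randomize(tvals, n_surrogates, rng)[:, idx]
        r_sur = _batch_partial(y, sur, np.column_stack(cond_cols))
        if r[i] >= 0:
            count = np.sum(r_sur >= r[i])
        else:
            count = np.sum(r_sur <= r[i])
        p[i] = (count + 1.0) / (len(r_sur) + 1.0)
    return LagCorrelationResult(
        predictor=str(target.name), lags=lags, r=r, p=p, n=len(years),
        partial=True, conditioning=tuple(conditioning),
    )


def _batch_partial(y: np.ndarray, targets: np.ndarray, cond: np.ndarray) -> np.ndarray:
    """Partial corr(y, target | cond) for many target rows at once."""
    n_sur = targets.shape[0]
    k = 2 + cond.shape[1]

    def _std(a, axis=0):
        a = a - a.mean(axis=axis, keepdims=True)
        sd = a.std(axis=axis, keepdims=True)
        return a / np.where(sd == 0, np.nan, sd)

    ys = _std(y[None, :], axis=1)[0]
    cs = _std(cond, axis=0)
    ts = _std(targets, axis=1)
    n = len(y)
    R = np.empty((n_sur, k, k))
    R[:, 0, 0] = R[:, 1, 1] = 1.0
    ryc = ys @ cs / n
    rcc = cs.T @ cs / n
    np.fill_diagonal(rcc, 1.0)
    R[:, 0, 2:] = ryc
    R[:, 2:, 0] = ryc
    R[:, 2:, 2:] = rcc
    R[:, 0, 1] = R[:, 1, 0] = ts @ ys / n
    rtc = ts @ cs / n
    R[:, 1, 2:] = rtc
    R[:, 2:, 1] = rtc
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        out = np.empty(n_sur)
        for s in range(n_sur):
            try:
                Ps = np.linalg.inv(R[s])
                out[s] = -Ps[0, 1] / np.sqrt(Ps[0, 0] * Ps[1, 1])
            except np.linalg.LinAlgError:
                out[s] = np.nan
        return out[np.isfinite(out)]
    out = -P[:, 0, 1] / np.sqrt(P[:, 0, 0] * P[:, 1, 1])
    return out[np.isfinite(out)]
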