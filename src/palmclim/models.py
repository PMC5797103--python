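"""Linear yield models: fitting, accuracy, nested comparison, stability, forecast.

A yield model regresses annual fresh-fruit-bunch yield (Mg ha-1) on a
declared list of lagged monthly predictors — local variables such as
regional-mean precipitation or maximum temperature (Model 1) plus remote
climate-mode indices such as Niño3, the Ningaloo index or the monsoon
index (Model 2).  A predictor is addressed by variable name, calendar
month and harvest-year offset (e.g. precipitation in July of the year
before harvest).  Fitting is ordinary least squares on the training
years; model improvement from the added indices is assessed by a nested
ANOVA F-test; accuracy is reported as ME / RMSE / MAE / MPE / MAPE /
MASE / ACF1 both in-sample and as bootstrap means; stability refits the
fixed predictor set on expanding training windows; forecasts carry 80%
and 95% prediction intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lags import predictor_at_calendar

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSpec",
    "YieldModel",
    "AccuracyReport",
    "NestedComparison",
    "resolve_design",
    "fit",
    "accuracy_metrics",
    "accuracy",
    "compare_nested",
    "stability",
    "forecast",
]


@dataclass(frozen=True)
class PredictorSpec:
    """One lagged predictor: variable name, calendar month, year offset."""

    variable: str
    month: int
    year_offset: int = 0

    def __post_init__(self):
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1..12, got {self.month}")
        if self.year_offset not in (0, -1, -2):
            raise ValueError(f"year_offset must be 0, -1 or -2, got {self.year_offset}")

    @property
    def label(self) -> str:
        mon = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"][self.month - 1]
        return f"{self.variable}_{mon}{self.year_offset:+d}".replace("+0", "0")


def resolve_design(
    specs: list[PredictorSpec],
    indices: dict[str, pd.Series],
    years: np.ndarray,
) -> pd.DataFrame:
    """Design matrix of resolved predictor values, one row per harvest year."""
    labels = [s.label for s in specs]
    dups = {l for l in labels if labels.count(l) > 1}
    if dups:
        raise ValueError(f"duplicate (collinear) predictors: {sorted(dups)}")
    cols = {}
    for spec in specs:
        if spec.variable not in indices:
            raise KeyError(f"no series available for predictor {spec.variable!r}")
        cols[spec.label] = predictor_at_calendar(
            indices[spec.variable], years, spec.month, spec.year_offset
        )
    return pd.DataFrame(cols, index=pd.Index(years, name="year"))


@dataclass
class YieldModel:
    """A fitted linear yield model for one region."""

    region: str
    specs: list[PredictorSpec]
    result: object  # statsmodels RegressionResults
    train_years: np.ndarray
    design: pd.DataFrame  # training design matrix (without constant)
    observed: np.ndarray
    trend_center: float | None = None  # year the linear trend term is centred on

    @property
    def intercept(self) -> float:
        return float(self.result.params.iloc[0])

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params.iloc[1:]

    @property
    def fitted(self) -> np.ndarray:
        return np.asarray(self.result.fittedvalues)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)

    @property
    def r_squared(self) -> float:
        return float(self.result.rsquared)

    def summary_dict(self) -> dict:
        return {
            "region": self.region,
            "predictors": [s.label for s in self.specs],
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "stderr": {k: float(v) for k, v in self.result.bse.items()},
            "r_squared": self.r_squared,
            "train_years": [int(self.train_years[0]), int(self.train_years[-1])],
        }


def fit(
    region: str,
    specs: list[PredictorSpec],
    yields: pd.Series,
    indices: dict[str, pd.Series],
    train_years: tuple[int, int] | None = None,
    include_trend: bool = False,
) -> YieldModel:
    """Ordinary least squares fit of yields on the declared predictors.

    ``include_trend`` adds a centred linear year term to the design, for
    series where a management/expansion trend would otherwise alias
    into the climate coefficients.
    """
    years = np.asarray(yields.index, dtype=int)
    if train_years is not None:
        keep = (years >= train_years[0]) & (years <= train_years[1])
        years = years[keep]
    y = yields.loc[years].to_numpy(dtype=float)
    if len(years) <= len(specs) + 1:
        raise ValueError(
            f"{len(years)} training years cannot identify {len(specs)} predictors"
        )
    X = resolve_design(specs, indices, years)
    trend_center = None
    if include_trend:
        trend_center = float(np.mean(years))
        X["TREND"] = years - trend_center
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs().to_numpy() - np.eye(X.shape[1])
        if X.shape[1] >= 2 and np.nanmax(corr) > 0:
            i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
            pair = f"{X.columns[i]!r} and {X.columns[j]!r}"
        else:
            pair = f"{X.columns[0]!r} and the intercept"
        raise ValueError(f"design matrix is rank deficient: {pair} are collinear")
    result = sm.OLS(y, Xc).fit()
    return YieldModel(
        region=region, specs=list(specs), result=result,
        train_years=years, design=X, observed=y, trend_center=trend_center,
    )


@dataclass
class AccuracyReport:
    """Goodness-of-fit metrics, in-sample and as bootstrap means."""

    ME: float
    RMSE: float
    MAE: float
    MPE: float
    MAPE: float
    MASE: float
    ACF1: float
    r2: float
    r: float
    bootstrap: dict = field(default_factory=dict)
    n_boot: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = {"in_sample": {k: getattr(self, k)
                              for k in ("ME", "RMSE", "MAE", "MPE", "MAPE", "MASE", "ACF1")}}
        if self.bootstrap:
            rows["bootstrap_mean"] = self.bootstrap
        return pd.DataFrame(rows).T


def _acf1(e: np.ndarray) -> float:
    e = e - e.mean()
    denom = e @ e
    if denom == 0:
        return 0.0
    return float(e[:-1] @ e[1:] / denom)


def accuracy_metrics(obs: np.ndarray, fit_: np.ndarray, naive_mae: float | None = None) -> dict:
    """ME/RMSE/MAE/MPE/MAPE/MASE/ACF1 for an (observed, fitted) pair.

    MASE scales MAE by the in-sample MAE of the naive one-step
    persistence forecast of the observed series (passed as
    ``naive_mae`` when the pairs are a bootstrap resample and the
    original time order is the meaningful scale).
    """
    obs = np.asarray(obs, dtype=float)
    fit_ = np.asarray(fit_, dtype=float)
    e = obs - fit_
    if naive_mae is None:
        naive_mae = float(np.mean(np.abs(np.diff(obs))))
    mae = float(np.mean(np.abs(e)))
    return {
        "ME": float(np.mean(e)),
        "RMSE": float(np.sqrt(np.mean(e**2))),
        "MAE": mae,
        "MPE": float(np.mean(100.0 * e / obs)),
        "MAPE": float(np.mean(np.abs(100.0 * e / obs))),
        "MASE": mae / naive_mae if naive_mae > 0 else np.inf if mae > 0 else 0.0,
        "ACF1": _acf1(e),
    }


def accuracy(
    model: YieldModel,
    n_boot: int = 10000,
    seed: int | None = None,
    method: str = "case",
) -> AccuracyReport:
    """Accuracy report with bootstrap means.

    ``method="case"`` (default) resamples (observed, fitted) pairs with
    replacement; ``method="residual"`` resamples residuals and adds them
    back onto the fitted values.  Either way the mean of each metric
    over replicates is reported, and the MASE denominator stays fixed at
    the original in-sample naive MAE because resampling destroys the
    time ordering that defines it.
    """
    if method not in ("case", "residual"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    obs, fit_ = model.observed, model.fitted
    if len(obs) < 3:
        raise ValueError("need at least 3 observations for an accuracy report")
    naive_mae = float(np.mean(np.abs(np.diff(obs))))
    base = accuracy_metrics(obs, fit_, naive_mae=naive_mae)
    rng = np.random.default_rng(seed)
    n = len(obs)
    resid = obs - fit_
    boots: dict[str, list[float]] = {k: [] for k in base}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if method == "case":
            m = accuracy_metrics(obs[idx], fit_[idx], naive_mae=naive_mae)
        else:
            m = accuracy_metrics(fit_ + resid[idx], fit_, naive_mae=naive_mae)
        for k, v in m.items():
            boots[k].append(v)
    report = AccuracyReport(
        **base,
        r2=model.r_squared,
        r=float(np.corrcoef(obs, fit_)[0, 1]),
        bootstrap={k: float(np.mean(v)) for k, v in boots.items()},
        n_boot=n_boot,
    )
    return report


@dataclass
class NestedComparison:
    """ANOVA table comparing a model with a nested sub-model."""

    res_df: tuple[int, int]
    rss: tuple[float, float]
    delta_df: int
    delta_ss: float
    F: float
    pvalue: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Res.Df": self.res_df,
                "RSS": self.rss,
                "Df": [np.nan, self.delta_df],
                "Sum of Sq": [np.nan, self.delta_ss],
                "F": [np.nan, self.F],
                "Pr(>F)": [np.nan, self.pvalue],
            },
            index=["model1", "model2"],
        )


def compare_nested(model1: YieldModel, model2: YieldModel) -> NestedComparison:
    """Nested ANOVA F-test: does the larger model reduce the RSS significantly?

    F = ((RSS1 - RSS2)/ΔDf) / (RSS2/Res.Df2) on (ΔDf, Res.Df2) degrees
    of freedom.  Requires model1's predictors to be a subset of model2's
    and identical training years.
    """
    s1 = {s.label for s in model1.specs}
    s2 = {s.label for s in model2.specs}
    if not s1 < s2:
        raise ValueError("model1 predictors must be a strict subset of model2's")
    if not np.array_equal(model1.train_years, model2.train_years):
        raise ValueError("models must share the same training years")
    rss1 = float(model1.result.ssr)
    rss2 = float(model2.result.ssr)
    df1 = int(model1.result.df_resid)
    df2 = int(model2.result.df_resid)
    ddf = df1 - df2
    dss = rss1 - rss2
    F = (dss / ddf) / (rss2 / df2) if rss2 > 0 else np.inf
    F = max(F, 0.0)
    p = float(stats.f.sf(F, ddf, df2))
    return NestedComparison(
        res_df=(df1, df2), rss=(rss1, rss2),
        delta_df=ddf, delta_ss=dss, F=float(F), pvalue=p,
    )


def stability(
    region: str,
    specs: list[PredictorSpec],
    yields: pd.Series,
    indices: dict[str, pd.Series],
    min_train: int = 5,
    include_trend: bool = False,
) -> pd.DataFrame:
    """Expanding-window refits of a fixed predictor set.

    Coefficients are estimated on the first ``min_train`` years and the
    remaining years are predicted; then on min_train + 1 years, and so
    on up to n - 1 training years.  Returns a tidy frame with one row
    per (training window, predicted year) holding the prediction, the
    observation and the window's maximum absolute error.
    """
    if min_train < len(specs) + 2:
        raise ValueError(
            f"min_train={min_train} too small for {len(specs)} predictors"
        )
    years = np.asarray(yields.index, dtype=int)
    rows = []
    for n_train in range(min_train, len(years)):
        train = (int(years[0]), int(years[n_train - 1]))
        model = fit(
            region, specs, yields, indices, train_years=train,
            include_trend=include_trend,
        )
        test_years = years[n_train:]
        X_new = resolve_design(specs, indices, test_years)
        if model.trend_center is not None:
            X_new["TREND"] = test_years - model.trend_center
        pred = model.result.predict(sm.add_constant(X_new, has_constant="add"))
        obs = yields.loc[test_years].to_numpy(dtype=float)
        max_err = float(np.max(np.abs(obs - np.asarray(pred))))
        for yy, pp, oo in zip(test_years, np.asarray(pred), obs):
            rows.append(
                {
                    "n_train": n_train,
                    "train_end": train[1],
                    "year": int(yy),
                    "predicted": float(pp),
                    "observed": float(oo),
                    "max_abs_error": max_err,
                }
            )
    return pd.DataFrame(rows)


def forecast(
    model: YieldModel,
    new_predictors: pd.DataFrame,
    levels: tuple[float, ...] = (0.80, 0.95),
) -> pd.DataFrame:
    """Point forecasts with prediction intervals at the requested levels.

    Uses the standard linear-regression prediction interval
    t_{1-a/2, df} * s * sqrt(1 + x'(X'X)^-1 x).  Logs a warning when a
    requested point lies far outside the training predictor range.
    """
    cols = [s.label for s in model.specs]
    missing = [c for c in cols if c not in new_predictors.columns]
    if missing:
        raise KeyError(f"new predictor values missing for {missing}")
    X_new = new_predictors[cols].copy()
    if model.trend_center is not None:
        if "TREND" in new_predictors.columns:
            X_new["TREND"] = new_predictors["TREND"]
        else:
            X_new["TREND"] = (
                np.asarray(new_predictors.index, dtype=float) - model.trend_center
            )
    lo = model.design.min(axis=0)
    hi = model.design.max(axis=0)
    span = (hi - lo).replace(0, np.nan)
    stretch = ((X_new - (lo + hi) / 2).abs() / span).max().max()
    if np.isfinite(stretch) and stretch > 3:
        logger.warning(
            "forecast point lies %.1fx outside the training predictor range", stretch
        )
    Xc = sm.add_constant(X_new, has_constant="add")
    out = {"point": np.asarray(model.result.predict(Xc))}
    pred = model.result.get_prediction(Xc)
    for level in levels:
        frame = pred.summary_frame(alpha=1.0 - level)
        pct = int(round(level * 100))
        out[f"lower_{pct}"] = frame["obs_ci_lower"].to_numpy()
        out[f"upper_{pct}"] = frame["obs_ci_upper"].to_numpy()
    return pd.DataFrame(out, index=new_predictors.index)
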