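# Methods and design notes

This note records the statistical procedures `palmclim` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish about real-data behaviour.

## Derived variables

**Saturation vapour pressure and relative humidity.** We use the
exponential form `e_sat(T) = a₁ exp[a₃ (T − T₀)/(T − a₄)]` with
a₁ = 6.1121 hPa, a₃ = 17.502, a₄ = 32.19 K, T₀ = 273.16 K, and
`RH = 100 · e_sat(Td)/e_sat(T)`. The constants produce pressure in hPa
(the unit of a₁); because RH is a ratio, the unit choice cancels and never
propagates. RH is not clipped at 100%: with reanalysis-style inputs the dew
point can exceed the air temperature, and we prefer to surface that (an
INFO log entry) rather than silently truncate.

**Reference evapotranspiration.** FAO56 Penman–Monteith for a short
reference crop, in mm d⁻¹. Soil heat flux G defaults to 0 — the FAO56
convention for daily steps. The slope Δ and psychrometric constant γ are
computed from the FAO56 standard parameterizations (`svp_slope`,
`psychrometric_constant`) when not supplied; callers with
reanalysis-derived values can pass them directly. Wind at 2 m comes from
10 m wind via the FAO56 log-profile factor 4.87/ln(678 − 5.42) ≈ 0.748.

**Vertically integrated moisture flux.** The mass-weighted integral of
W·q between the surface pressure and 250 hPa, per wind component, on 21
levels / 20 pressure differences. The layer rule is trapezoidal: each
layer contributes the mean of its bounding-level W·q times δp/g, with
g = 9.807 m s⁻². Linearity in both q and W, and agreement with a
brute-force trapezoidal sum to 1e-10, are enforced by tests.

**Indices.** All spatial box means are cos(latitude)-weighted (the
weighting convention is a package choice; at the near-equatorial boxes it
is almost inert, at the Ningaloo box it matters slightly). The monsoon
index is the difference between the area-mean 850 hPa zonal wind anomaly
over 85–95°E, 7.5–12.5°N and the area-mean meridional wind anomaly over
120–122.5°E, 0–8.75°N. Ningaloo and other SST boxes are configuration
parameters, not hard-coded: the default Ningaloo strip is 108–116°E,
28–22°S.

**Preprocessing.** Anomalies are deviations from the per-calendar-month
climatology over a baseline year range (default: the full span), with a
per-point linear trend removed. The climatology and trend are estimated
in a *single* joint least-squares fit (12 month dummies + centred linear
term) rather than sequentially: month dummies are not orthogonal to the
trend, so the sequential version is neither exactly idempotent nor exact
on a pure trend, while the joint fit is an orthogonal projection — running
it twice changes nothing, a pure linear series maps to zero, a pure
seasonal cycle maps to zero. The sequential and joint versions agree to
r > 0.999 on realistic series. The optional 3-month running mean is
centred, with shortened windows at the endpoints so series length (and
hence lag bookkeeping) is preserved.

## Yield variation rate and year classification

The trend in annual yields is estimated by loess: tricube weights over
the k = int(span·n) nearest neighbours (the truncation rule of the classic
reference implementations; the k-th neighbour carries zero tricube weight,
so this differs from a ceil rule only at the series ends), local
polynomials of degree 1, no robustness iterations, span 0.32. The
variation rate is 100·(yield − trend)/trend — a scale-free percentage;
this is stated as a methodological assumption, being the natural reading
of a "year-to-year variation rate" in percent. Low/high years are those
with rate below −k·SD / above +k·SD with k = 0.7 and sample SD (n−1
denominator; configurable). k = 0.7 rather than 1.0 reflects the short
(≈28-year) series: a full ±1 SD leaves too few years per composite group.

## Composites

Time-series composites span 48 relative months, January three years
before harvest through December of the harvest year, so the windows of
neighbouring years overlap by construction. Group means are shown as
deviations from the all-years mean at each relative month, so the low
and high curves share a common reference. Seasonal map composites use
SON of the year before harvest, DJF spanning the year boundary (assigned
to the harvest year of its January/February), and MAM/JJA of the harvest
year.

Significance is by permutation of year labels over the union of low and
high years only — normal years never enter the null, matching the
two-group contrast being plotted. Scalar fields use the pooled-variance
two-sample t statistic; two-component (flux) vectors use the two-sample
Hotelling T² with pooled covariance, referenced to its permutation
distribution rather than the F approximation. p-values use the
(b+1)/(B+1) estimator, so they are never exactly zero. Permutation draws
reassign a subset of size min(n_low, n_high); since |t| and T² depend
only on the unordered partition, p-values are exactly invariant under
swapping the low/high labels. For the 48-month composites the pooled
sample is permuted independently at each relative month (each month is a
separate test, as plotted); map composites share one year-relabelling
across cells within a draw, preserving spatial coherence of the null
field. No field-significance or multiple-testing control is applied
across grid cells — masks are per-point 95% decisions, and that is a
known limitation.

## Lagged and partial correlations

Lag ℓ pairs the yield of harvest year y with the predictor value ℓ months
before December of y (so Mar₀ is lag 9, Jul₋₁ is lag 17); the convention
lives in one helper (`palmclim.lags`) and is exhaustively unit-tested.
Lags run 0–30 months. By default the correlations use the yield variation
rate (the interannual signal) rather than raw yields; this is switchable.

Partial correlations are computed by precision-matrix inversion: with R
the correlation matrix of (yield, target, conditioning…) and P = R⁻¹,
partial r = −P₁₂/√(P₁₁P₂₂). ENSO (Niño3) is the conditioning variable
for Modoki, the dipole index, Ningaloo and the monsoon index, isolating
each mode's direct association under the (strong) assumption of linear
independence among modes; no further orthogonalization is attempted. A
singular or numerically near-singular correlation matrix raises an error
naming the most collinear pair.

**Random-phase significance.** Surrogates of the (monthly, longer,
autocorrelated) predictor series keep the amplitude spectrum of the
original and randomize Fourier phases with conjugate symmetry; the DC
component is untouched (the surrogate mean equals the original exactly)
and the Nyquist component, when present, is kept real via a random sign.
The annual yield series stays fixed, and each surrogate is sampled at the
same lagged months before correlating. The reported p is directional —
the fraction of surrogate correlations at least as extreme in the
direction of the observed sign, with the observed value counted in the
null set. Because the direction is chosen after seeing the sign, this p
rejects at twice its nominal threshold under the null; the
`significant_at(level)` helper therefore compares it with (1 − level)/2.
With that correction the measured size of the test is 0.04 at the 95%
level for an AR(1) (φ = 0.6) monthly predictor against independent
yields (500 replicates × 1000 surrogates) — the band the test is designed
to hold under autocorrelation. A two-sided option exists but is off by
default.

## Yield models

Predictors are declared, not selected: a `PredictorSpec` names a
variable, a calendar month, and a harvest-year offset (0, −1, −2),
mirroring the `VAR_Monₖ` subscript convention. An optional exhaustive
search helper is deliberately *not* provided — automated selection is out
of scope, and the declared-predictor workflow keeps the stability and
ANOVA analyses honest. Models are fit by OLS on raw annual yields
(Mg ha⁻¹), not the variation rate, with an optional centred linear year
term (`include_trend`) for series where a management/expansion trend
would otherwise alias into climate coefficients.

Accuracy: ME = mean(obs − fit), RMSE, MAE, MPE/MAPE in percent of the
observation, MASE = MAE divided by the in-sample MAE of the naive lag-1
persistence forecast, and the lag-1 autocorrelation of residuals. The
bootstrap resamples (obs, fit) pairs with replacement and reports the
mean of each metric over replicates (a residual bootstrap is available by
flag); the MASE denominator stays fixed at the original in-sample naive
MAE because resampling destroys the time ordering that defines it. Both
the plain in-sample metrics and the bootstrap means are reported, since
either could be the quantity a reader wants.

Nested comparison: F = ((RSS₁−RSS₂)/ΔDf)/(RSS₂/Res.Df₂) with the
F-distribution p-value; cross-checked against `statsmodels.anova_lm` in
tests. Stability: with the predictor set fixed, coefficients are re-fit
on expanding windows (first 5 years, first 6, …, n−1) and all subsequent
years are predicted; the maximum absolute prediction error per window
summarizes drift. Forecasts use the standard linear-regression prediction
interval t·s·√(1 + x'(X'X)⁻¹x) at 80% and 95%; a point far outside the
training predictor range triggers a log warning, not an error.

## Synthetic data: what it emulates and what it does not

The generator produces ~31 years of monthly data (28 harvest years plus
3 spin-up years so every composite window and 30-month lag exists):

- **ENSO-like driver**: monthly AR(1) with persistence 0.85 and
  innovation SD multiplicatively phase-locked to boreal winter (strength
  0.4), rescaled to unit stationary SD — reproducing the winter-peaking
  life cycle the composites rely on.
- **Fields**: per variable, a truncated-Fourier climatology (annual +
  semiannual harmonics with Malaysian-plausible means: ~200 mm month⁻¹
  precipitation, 31/23 °C max/min temperature) + a teleconnection weight
  times the driver + spatially correlated Gaussian noise (isotropic
  exponential covariance, 8° e-folding). Weights follow the canonical
  El Niño response over the Maritime Continent (drier, warmer, sunnier).
- **SST domain**: 40–290°E, 30°S–30°N at 5°, carrying an
  equatorial-Pacific pattern proportional to the driver (peak 1.1 °C per
  unit driver near 235°E) plus correlated noise; Niño3 and Modoki-style
  boxes therefore track the driver while the Ningaloo and dipole boxes
  are noise-driven.
- **Yields**: intercept 18 Mg ha⁻¹ + a small linear trend
  (0.03 Mg ha⁻¹ yr⁻¹) + a declared linear model on lagged regional-mean
  anomalies — one precipitation lag from the pre-harvest year plus two
  remote SST-index terms (coefficients 0.0158, −0.678, −0.999), the shape
  of the two-stage country-scale model — + Gaussian noise of SD
  0.35 Mg ha⁻¹ (≈2% MAPE). Yields sit in a 15–21 Mg ha⁻¹ range; the
  generating coefficients and the implied low/high labels are returned as
  ground truth.
- **Ground-truth labels** are computed with the statsmodels lowess
  smoother, deliberately a different implementation from the package's
  own loess, so the label-agreement test is a genuine cross-check of two
  independent smoothers.

Not emulated: realistic Malaysian geography or coastlines, monsoon
dynamics, the Indian Ocean Dipole and Modoki as dynamically separate
modes (their synthetic indices are noise or driver-correlated box means),
haze/fire radiative effects, or any nonlinearity in the yield response.
Passing tests therefore establish that the *machinery* is correct and
calibrated — oracle equality, permutation-test level, CI and
prediction-interval coverage, parameter recovery — not that the fitted
coefficients or R² values transfer to real MPOB/reanalysis data. The
real-data path is exercised by `scripts/validate_real_data.py` against a
user-supplied yields CSV.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  pipeline stage takes a seed and the run manifest records it, so any
  stage can be reproduced bit-for-bit.
- Permutation/surrogate/bootstrap counts default to the full 10000 (series
  composites, surrogates, bootstrap) and 5000 (map composites); tests and
  the `--smoke` CLI flag use reduced counts (a few hundred) with the
  corresponding Monte-Carlo tolerances — simulation sizes in the test
  suite (200 dataset replicates for recovery, 500 for calibration and
  coverage) were chosen to keep Monte-Carlo error comfortably inside the
  asserted bands.
- Degenerate inputs fail loudly: constant series cannot be
  phase-randomized or classified, empty masks and non-intersecting boxes
  raise, rank-deficient designs name the collinear predictors.
- Gridded I/O uses xarray's classic-NetCDF (scipy) backend; indices and
  yields travel as two-column CSV; configs and manifests as YAML.
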