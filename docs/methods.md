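# Methods

This note documents the models and numerical choices behind `ringclim`,
in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Ring-width model and standardization

Measured ring widths `w_t` (mm, 0.01 mm resolution; width 0 encodes a
locally absent ring) are assumed to factor multiplicatively into a
slowly varying biological growth level and a dimensionless year-to-year
signal:

    w_t = g(t) * exp(s_t)

Standardization estimates `g` with a cubic smoothing spline and forms
quotient indices `I_t = w_t / g_hat(t)`, which have mean ~ 1 and carry
the high-frequency signal. The multiplicative form is what makes
quotient (rather than difference) detrending appropriate, and it is the
form the synthetic generator simulates, so generator and estimator
share assumptions by construction.

### Spline cutoff parameterization

The growth curve is a smoothing spline minimizing
`sum (w - f)^2 + lam * int f''^2`. On equally spaced interior points
this penalty acts as a low-pass filter with amplitude response
`1/(1 + lam * omega^4)`, giving the classical analytic mapping
`lam = (P/(2*pi))^4` for a 50% response at wavelength `P`. The
conventional choice `P = 0.67 * n` ("67% spline") puts only ~1.5 sine
cycles inside the series, where the natural-spline boundary passes
substantially more amplitude than the interior-filter formula predicts:
measured realized attenuation is 0.56-0.65 (phase-dependent) instead of
0.50, while the analytic value is accurate for wavelengths much shorter
than the series (measured 0.51 at 20 cycles).

`ringclim` therefore calibrates `lam` against the finite series
directly: bisection on `log(lam)` of the realized amplitude response of
a cutoff-wavelength sine spanning the series, averaged over sine and
cosine phase (`chronology.calibrated_lambda`, 48 bisection steps,
cached per series length). This reproduces the analytic value in the
many-cycle limit and gives a realized cutoff response of 0.49-0.51 for
all phases at `P = 0.67 n`. A series whose spline dips non-positive
falls back to a linear fit, then to the horizontal mean, with a
warning; a quotient needs a positive divisor.

### Prewhitening and chronologies

Each index series is optionally prewhitened with an autoregressive
model: consecutive-lag AR(p), p = 0..p_max (default 10), compared by
AIC via `statsmodels.ar_select_order`, refitted by conditional least
squares; candidates with a root on or inside the unit circle are
skipped. Residuals are re-centered to mean 1 so STD (detrended) and
RES (detrended + prewhitened) chronologies share units; the first p
years are undefined (AR ramp-in), as are missing rings.

Year-by-year averaging uses Tukey's biweight robust location: median
start, scale fixed at the initial MAD, tuning constant c = 9, weights
`(1 - u^2)^2`, iterated to 1e-8 (max 50 iterations). With the scale
fixed the iteration is a monotone contraction; when MAD = 0 (at least
half the values identical) the median is returned without iteration.
Missing rings are excluded from the mean and from all correlations — a
locally absent ring is not zero growth at stand level.

Signal strength is tracked in running windows (default 50 years,
overlap 25): `rbar` is the mean pairwise Pearson correlation among
series fully covering the window, and the expressed population signal
is `EPS = N*rbar / (N*rbar + (1 - rbar))`. EPS >= 0.85 is the
conventional adequacy threshold; the pipeline warns (but continues)
when no window reaches it. STD indices are used for rbar/EPS by
default, switchable in configuration.

## Crossdating statistics

GLK (Gleichlaufigkeit) scores the first differences of the overlap:
1 for matching nonzero signs, 0.5 when exactly one difference is zero,
0 otherwise; reported as a percentage. Ties get half weight following
the usual convention.

The Baillie-Pilcher t first high-passes both series (percent of a
centered 5-year moving average, window truncated at the ends, then
natural log), then converts the Pearson correlation of the filtered
overlap: `t = r * sqrt((n-2)/(1-r^2))`; `|r| = 1` (a series against
itself) returns an infinite sentinel. Minimum overlap: 12 years.

Calibration caveat: the 5-term centered moving-average high-pass
induces negative autocorrelation in the filtered series (analytically
rho_1 = -0.30, rho_2 = -0.35 under white noise), which inflates the
null variance of `r` by ~1.45. The unadjusted t statistic is therefore
anti-conservative: for independent noise at n = 100, `|t| > 2.63` (the
nominal two-sided 1% point) occurs in ~2.9% of pairs (Monte-Carlo,
matching the analytic prediction). This is a property of the classical
statistic, kept here deliberately; treat t_BP thresholds as
conventional dating scores, not exact p-values.

## SPEI

The climatic water balance `D = P - PET` uses Thornthwaite PET
(temperature and latitude only): per-year heat index
`I = sum (T_m/5)^1.514` over months with `T_m > 0`, exponent
`a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239`,
`PET_m = 16 (10 T_m / I)^a` corrected by day length (from solar
declination at mid-month) and month length; `PET = 0` for freezing
months. Temperature-only PET is the implementable choice when only
monthly temperature and precipitation exist; precomputed PET from any
other method can be passed in instead.

`D` is summed over a k-month window ending in each month (k = 3
default, 6 supported; the first k-1 months are undefined). Per
calendar month a 3-parameter log-logistic distribution is fitted to
the calibration period (default: the full record) by unbiased
probability-weighted moments (the alpha-type PWMs with weights
`(1-F)^r`). For near-symmetric or left-skewed months the joint PWM
solution yields a negative (shape, scale) pair — the reflected
log-logistic — which is accepted as long as `|shape| > 1`; its CDF is
increasing either way. Fitted probabilities are clipped to
`[1e-6, 1 - 1e-6]` (bounding |SPEI| at ~4.75) and mapped through the
exact standard-normal quantile. Within the calibration period each
calendar month has mean ~ 0 and SD ~ 1 by construction; values outside
it are standardized with the calibration parameters. Because the PWM
shape estimate depends only on shift-invariant moment combinations,
refitting a constant-shifted `D` reproduces identical SPEI values
(tested).

## Percentile anomaly classification

A value is ranked against a reference period (default 1961-1990) with
the Weibull plotting position: `percentile = 100 * m/(n+1)` where `m`
counts reference values `<=` the value. Classes: `<2` extremely
dry/cold, `[2,9)` very dry/cold, `[9,25)` dry/cold, `[25,75]` normal,
`(75,91]` wet/warm, `(91,98]` very wet/warm, `>98` extremely wet/warm
— exhaustive and mutually exclusive, both endpoints of the normal band
normal. Temperature is ranked directly, so high percentiles are warm;
annual values use mean temperature and total precipitation.

## Climate-growth analysis

Predictors are monthly temperature, precipitation and SPEI of the
growth year (January-September by default) plus named seasonal
aggregates ("P Apr-Aug" sums precipitation, "T Jul+Aug" averages
temperature). The point estimate per predictor is the Pearson
correlation with the chronology (RES by default) over common years;
confidence intervals come from paired resampling of years with
replacement (default 1000 resamples, percentile method); a predictor
is significant when its 95% interval excludes zero. No
multiple-testing correction is applied across predictors — read wide
screens accordingly. The percentile CI is known to be slightly
anti-conservative at small n: measured type-I error is ~5.6% at n = 70
and ~8.5% at n = 25 (the moving-window size), which matters when
interpreting isolated significant windows.

Temporal stability uses 25-year windows advancing by 1 year, each
window bootstrapped independently from a per-window substream of the
seed. Spatial fields correlate the chronology with each grid cell's
seasonal aggregate and mask cells at two-sided Pearson p < 0.05; cells
with fewer than 30 common years or masked (ocean) cells stay missing.

## Pointer years

A year is a pointer year when at least 70% (threshold, must exceed
0.5) of at least 70 trees (min_trees) change raw ring width in the
same direction versus the prior year. A tree with a missing ring in
either year, or an exact tie, counts toward the tree total for that
year but toward neither direction, so `frac_up + frac_down <= 1`.
Raising the threshold can only remove pointer years (tested as a
monotonicity sweep). Detected years are joined with the monthly
(January-September) and annual temperature/precipitation percentiles;
years outside climate coverage are kept but flagged unattributed.

## Synthetic data: what it emulates, and what it does not

The generator produces the data the analysis assumes:

    w[i,t] = A * exp(-k * age[i,t])
             * exp(beta_t * z_t + c_t + e[i,t]) * factor_t

with `z_t` the standardized seasonal climate aggregate (default:
June-August precipitation sum), `c_t` a stand-level AR(1) disturbance
common to all trees, `e[i,t]` independent per-tree AR(1) noise,
`factor_t` planted pointer-year factors, and widths rounded to
0.01 mm. Germination years are staggered so sample depth varies.
Climate is a sinusoidal temperature seasonality plus Gaussian noise
and gamma monthly precipitation with a configurable warm-season
(April-September) share; the gridded counterpart mixes the base
series with independent cell noise whose weight decays exponentially
with distance from a focal cell, so the expected cell-base correlation
equals the mixing weight.

The common term `c_t` is essential: with tens of trees, independent
tree noise averages out of the chronology, and without a shared
disturbance the chronology-signal correlation would approach 1
regardless of noise levels. The defaults (beta = 0.15, common SD 0.2,
tree SD 0.45, phi = 0.5) put the chronology-level climate correlation
at `beta/sqrt(beta^2 + sigma_c^2) ~ 0.6` and the inter-series
correlation at ~0.24, both typical of temperate broadleaf stands.

Known limitations. (1) Pointer-year frequency: the same variance
decomposition that fixes the chronology-level correlation makes
whole-stand coherent years more common than in real stands (~20-40 per
century at the 70% threshold versus ~10-20 in field data); real pointer
years arise partly from threshold-like physiological responses the
log-linear model does not represent. (2) A planted single-year factor
deterministically produces a rebound the following year (widths return
to the baseline, so ~100% of trees increase after a planted negative
year); the detector correctly reports these as opposite-sign pointer
years, and validation accounts for them explicitly. (3) The two
simulated regions draw independent climates, so inter-regional
agreement statistics on synthetic data hover at their null values;
the generator makes no attempt to emulate shared synoptic forcing or
the stand-structure differences between real regions. (4) Real-data
features absent from the generator: dating errors, size-dependent
(non-age) trends, disturbance pulses, juvenile suppression, and
missing-ring clustering in drought years.

## Validation experiment sizes

The statistical validation suite uses stands of 80 trees over 100
years (50 replicate seeds) for signal recovery and moving-window
localization; 200 replicates of 20 null predictors over 70 years for
type-I calibration; 1000 independent pairs for the t_BP null; 500
random pairs for the GLK oracle; and 200 random files per dialect for
ring-width I/O round-trips. Seeds are derived from a single master
seed via stage-name salting (`pipeline.derive_seed`), so every stage
is reproducible in isolation.
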