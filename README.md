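# ringclim

Dendroecological climate-growth analysis in Python: from raw tree-ring
widths to standardized chronologies, drought indices, bootstrapped
climate-growth correlations and pointer-year detection.

`ringclim` is aimed at dendroecologists and forest ecologists who want
the classical analysis chain — the one usually assembled from dplR,
treeclim and ad-hoc scripts — as one tested, scriptable Python package,
together with a synthetic-data generator that produces ring-width and
climate inputs with known ground truth for method validation.

## What it computes

* **Standardization.** Each ring-width series `w_t` is divided by a
  cubic smoothing spline `g_hat(t)` whose frequency response is 50% at
  a wavelength of 67% of the series length, giving dimensionless
  indices `I_t = w_t / g_hat(t)` with mean ~ 1. Indices are optionally
  prewhitened with a minimum-AIC autoregressive model, and series are
  combined year-by-year with Tukey's biweight robust mean into STD and
  RES chronologies.
* **Signal statistics.** Running mean inter-series correlation `rbar`
  and the expressed population signal
  `EPS = N*rbar / (N*rbar + (1 - rbar))` (adequacy convention:
  EPS >= 0.85).
* **Crossdating statistics.** Gleichlaufigkeit (GLK%, sign agreement of
  year-to-year changes) and the Baillie-Pilcher
  `t = r * sqrt((n-2)/(1-r^2))` on 5-year high-pass filtered series.
* **Drought index.** SPEI at a k-month scale: water balance
  `D = P - PET` (Thornthwaite PET), k-month sums fitted per calendar
  month with a 3-parameter log-logistic distribution by unbiased
  probability-weighted moments, mapped through the standard-normal
  quantile.
* **Climate-growth correlations.** Pearson correlations of a
  chronology with monthly/seasonal climate predictors, with percentile
  confidence intervals from paired bootstrap resampling of years;
  25-year moving windows for temporal stability; per-cell correlation
  fields against gridded climate with a p < 0.05 significance mask.
* **Pointer years.** Years in which >= 70% of >= 70 trees change ring
  width in the same direction, attributed to monthly and annual
  temperature/precipitation percentile classes relative to a
  1961-1990-style reference period.

File formats: Tucson/RWL decadal ring widths (0.01 and 0.001 mm
dialects, byte-exact round-trip), a fixed CSV schema for monthly
climate, and NetCDF for gridded fields. See `docs/methods.md` for the
models, assumptions and numerical choices.

## Worked example

Generate a synthetic stand of 40 beech-like trees whose growth responds
to June-August precipitation, build its chronology, and ask which
climate variables explain it:

```python
from ringclim.synthetic import SyntheticParams, gen_climate, gen_ring_widths
from ringclim.pipeline import standardize
from ringclim.climate_indices import spei
from ringclim.climate_growth import build_predictors, bootstrap_correlation

climate = gen_climate(100, seed=7, warm_season_share=0.6)
stand, truth = gen_ring_widths(SyntheticParams(n_trees=40, n_years=100, seed=8), climate)

region = standardize(stand)          # spline detrend + AR prewhiten + biweight mean
print(region.signal_stats.round(3))  # running rbar / EPS / sample size

spei3 = spei(climate, k=3)
X = build_predictors(climate, spei_series=spei3,
                     aggregates=["P Jun-Aug", "P Apr-Aug", "T Jul+Aug"])
corr = bootstrap_correlation(region.chron_res.to_series(), X, n_boot=1000, seed=9)
print(corr[corr["valid"]].sort_values("r", ascending=False).head(5)
          [["r", "ci_lo", "ci_hi", "significant", "n"]].round(3))
```

Output:

```
       rbar    eps   n
year
1946  0.395  0.953  31
1971  0.283  0.941  40
1996  0.241  0.927  40
               r  ci_lo  ci_hi  significant    n
predictor
P Jun-Aug  0.711  0.592  0.805         True  100
P Apr-Aug  0.668  0.507  0.778         True  100
SPEI3 Aug  0.664  0.531  0.761         True  100
SPEI3 Jul  0.584  0.450  0.692         True  100
P Jun      0.533  0.398  0.663         True  100
```

Every EPS window clears the 0.85 adequacy threshold, and the planted
June-August precipitation aggregate comes out as the strongest
predictor (r = 0.71 with a bootstrap CI excluding zero), with the
August 3-month SPEI — which integrates the same summer water balance —
close behind. That is the expected signature: the generator planted a
chronology-level correlation of about 0.6 with summer precipitation,
and one realization recovers it within sampling noise.

The same analysis is scriptable from the shell: `ringclim simulate`,
`ringclim chrono`, `ringclim spei`, `ringclim climgrowth`,
`ringclim movewin`, `ringclim spatial`, `ringclim pointer`,
`ringclim crossdate`, and `ringclim run-all --config config.yaml` for
the full bundle (chronology TSV, SPEI and percentile tables,
correlation and moving-window CSVs, pointer-year attribution, manifest
and log).

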