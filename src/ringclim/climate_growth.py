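"""Climate-growth analysis: bootstrapped correlation functions,
moving-window stability, and spatial correlation fields.

The basic design mirrors the bootstrapped correlation-function family:
the point estimate is the Pearson correlation between a chronology and
each monthly or seasonal predictor over their common years; confidence
intervals come from paired resampling of years with replacement
(percentile method); a predictor is significant when its 95% interval
excludes zero.  No multiple-testing correction is applied across
predictors — each bar stands on its own, as is conventional for monthly
correlation functions; read wide predictor screens accordingly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ringclim.core import MONTH_NAMES, ClimateTable, GriddedClimate
from ringclim.climate_indices import SPEISeries

__all__ = [
    "parse_aggregate",
    "build_predictors",
    "bootstrap_correlation",
    "moving_correlation",
    "MovingWindowResult",
    "spatial_correlation",
    "SpatialCorrField",
]

_MON_ABBR = {name[:3].capitalize(): i + 1 for i, name in enumerate(MONTH_NAMES)}


def parse_aggregate(spec: str) -> tuple[str, list[int], str]:
    """Parse an aggregate label like ``"P Apr-Aug"`` or ``"T Jul+Aug"``.

    Returns (variable, months, stat) where variable is one of ``T``,
    ``P`` or ``SPEI``; ranges (``-``) expand to consecutive months,
    ``+`` lists individual months.  Precipitation aggregates are summed,
    temperature and SPEI aggregates are averaged.
    """
    m = re.fullmatch(r"\s*(T|P|SPEI\d*)\s+(.+?)\s*", spec)
    if not m:
        raise ValueError(f"cannot parse aggregate {spec!r}")
    var, months_part = m.group(1), m.group(2)
    months_part = months_part.replace("–", "-")  # tolerate en-dash
    if "-" in months_part:
        lo, hi = months_part.split("-")
        lo_m, hi_m = _MON_ABBR.get(lo.strip()), _MON_ABBR.get(hi.strip())
        if lo_m is None or hi_m is None or hi_m < lo_m:
            raise ValueError(f"bad month range in {spec!r}")
        months = list(range(lo_m, hi_m + 1))
    else:
        months = []
        for tok in months_part.split("+"):
            mm = _MON_ABBR.get(tok.strip())
            if mm is None:
                raise ValueError(f"unknown month {tok.strip()!r} in {spec!r}")
            months.append(mm)
    stat = "sum" if var == "P" else "mean"
    return var, months, stat


def build_predictors(
    climate: ClimateTable,
    spei_series: SPEISeries | None = None,
    aggregates: list[str] | None = None,
    months: range = range(1, 10),
) -> pd.DataFrame:
    """Year x predictor matrix of monthly and seasonal climate variables.

    Columns are monthly temperature and precipitation of the growth year
    (January-September by default), monthly SPEI when a fitted
    :class:`SPEISeries` is given, and any named aggregates ("P Apr-Aug"
    sums precipitation April through August of each year; "T Jul+Aug"
    averages the two monthly temperatures).
    """
    cols: dict[str, pd.Series] = {}
    for m in months:
        abbr = MONTH_NAMES[m - 1].capitalize()
        cols[f"T {abbr}"] = climate.temperature[m]
        cols[f"P {abbr}"] = climate.precipitation[m]
        if spei_series is not None:
            cols[f"SPEI{spei_series.scale} {abbr}"] = spei_series.values[m]
    for spec in aggregates or []:
        var, agg_months, stat = parse_aggregate(spec)
        if var == "T":
            tab = climate.temperature
        elif var == "P":
            tab = climate.precipitation
        else:
            if spei_series is None:
                raise ValueError(f"aggregate {spec!r} needs a SPEI series")
            tab = spei_series.values
        sub = tab[agg_months]
        cols[spec] = sub.sum(axis=1) if stat == "sum" else sub.mean(axis=1)
    return pd.DataFrame(cols)


def _boot_corr_matrix(y: np.ndarray, x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pearson r for each bootstrap row of paired resamples."""
    yb = y[idx]
    xb = x[idx]
    yc = yb - yb.mean(axis=1, keepdims=True)
    xc = xb - xb.mean(axis=1, keepdims=True)
    num = np.sum(yc * xc, axis=1)
    den = np.sqrt(np.sum(yc**2, axis=1) * np.sum(xc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_correlation(
    chron: pd.Series,
    predictors: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    min_years: int = 30,
) -> pd.DataFrame:
    """Bootstrapped Pearson correlations of a chronology with predictors.

    For each predictor the common (finite) years are found, the Pearson
    r is computed, and ``n_boot`` paired resamples of years (drawn with
    replacement) give a percentile confidence interval at level
    ``1 - alpha``.  The result has one row per predictor with columns
    ``r, ci_lo, ci_hi, significant, n, valid``.  A zero-variance
    predictor is flagged ``valid=False`` rather than dropped.
    Deterministic for a fixed integer seed.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # align once; per-predictor work is pure numpy
    y_all = chron.reindex(predictors.index).to_numpy(dtype=float)
    x_all = predictors.to_numpy(dtype=float)
    y_ok = np.isfinite(y_all) & (y_all != 0)  # index 0 = absent value convention
    rows = []
    for j, name in enumerate(predictors.columns):
        keep = y_ok & np.isfinite(x_all[:, j])
        n = int(keep.sum())
        if n < min_years:
            raise ValueError(f"predictor {name!r}: only {n} common years (< {min_years})")
        y = y_all[keep]
        x = x_all[keep, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((name, np.nan, np.nan, np.nan, False, n, False))
            continue
        r = float(np.corrcoef(y, x)[0, 1])
        idx = rng.integers(0, n, size=(n_boot, n))
        rb = _boot_corr_matrix(y, x, idx)
        rb = rb[np.isfinite(rb)]
        lo, hi = np.percentile(rb, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        sig = bool(lo > 0.0 or hi < 0.0)
        rows.append((name, r, float(lo), float(hi), sig, n, True))
    return pd.DataFrame(
        rows, columns=["predictor", "r", "ci_lo", "ci_hi", "significant", "n", "valid"]
    ).set_index("predictor")


@dataclass
class MovingWindowResult:
    """Per-window correlation and significance matrices."""

    window: int
    offset: int
    start_years: np.ndarray
    r: pd.DataFrame            # window-start-year x predictor
    significant: pd.DataFrame  # same shape, bool

    @property
    def n_windows(self) -> int:
        return len(self.start_years)


def moving_correlation(
    chron: pd.Series,
    predictors: pd.DataFrame,
    window: int = 25,
    offset: int = 1,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MovingWindowResult:
    """Bootstrapped correlations in moving windows of years.

    Windows of ``window`` years advance by ``offset``; each window runs
    the same bootstrap as :func:`bootstrap_correlation` (with a
    per-window substream of the seed, so results are reproducible and
    windows are independent).
    """
    years = chron.dropna().index
    years = years[chron.loc[years] != 0]
    y0, y1 = int(years.min()), int(years.max())
    n_years = y1 - y0 + 1
    if window > n_years:
        raise ValueError(f"window {window} longer than the {n_years}-year record")
    starts = np.arange(y0, y1 - window + 2, offset)
    streams = np.random.SeedSequence(seed).spawn(len(starts))
    r_rows, s_rows = [], []
    for start, stream in zip(starts, streams):
        sel = (chron.index >= start) & (chron.index <= start + window - 1)
        res = bootstrap_correlation(
            chron.loc[sel],
            predictors.loc[(predictors.index >= start) & (predictors.index <= start + window - 1)],
            n_boot=n_boot,
            seed=np.random.default_rng(stream),
            alpha=alpha,
            min_years=min(window, 10),
        )
        r_rows.append(res["r"])
        s_rows.append(res["significant"])
    r = pd.DataFrame(r_rows, index=pd.Index(starts, name="window_start"))
    sig = pd.DataFrame(s_rows, index=pd.Index(starts, name="window_start")).astype(bool)
    return MovingWindowResult(window=window, offset=offset, start_years=starts, r=r, significant=sig)


@dataclass
class SpatialCorrField:
    """Per-cell correlation of a chronology with a gridded climate field."""

    latitudes: np.ndarray
    longitudes: np.ndarray
    r: np.ndarray              # (nlat, nlon), NaN where missing
    p: np.ndarray
    significant: np.ndarray    # bool; p < alpha and cell not missing
    alpha: float
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Long-form table of cells (lat, lon, r, p, significant)."""
        la, lo = np.meshgrid(self.latitudes, self.longitudes, indexing="ij")
        return pd.DataFrame(
            {
                "lat": la.ravel(),
                "lon": lo.ravel(),
                "r": self.r.ravel(),
                "p": self.p.ravel(),
                "significant": self.significant.ravel(),
            }
        )


def spatial_correlation(
    chron: pd.Series,
    grid: GriddedClimate,
    months: list[int],
    stat: str | None = None,
    period: tuple[int, int] | None = None,
    alpha: float = 0.05,
    min_overlap: int = 30,
) -> SpatialCorrField:
    """Correlate a chronology with every grid cell's seasonal aggregate.

    ``months`` selects the months aggregated within each year
    (precipitation is summed, other variables averaged, unless ``stat``
    overrides).  Cells are tested with a two-sided Pearson test and the
    significance mask is ``p < alpha``.  Masked cells and cells with
    fewer than ``min_overlap`` common years stay NaN / not significant.
    """
    if stat is None:
        stat = "sum" if grid.variable == "precipitation" else "mean"
    years = grid.years
    if period is not None:
        keep = (years >= period[0]) & (years <= period[1])
    else:
        keep = np.ones(len(years), dtype=bool)
    ch = chron.dropna()
    ch = ch[ch != 0]

    nlat, nlon = len(grid.latitudes), len(grid.longitudes)
    r = np.full((nlat, nlon), np.nan)
    p = np.full((nlat, nlon), np.nan)
    sig = np.zeros((nlat, nlon), dtype=bool)
    mcols = [m - 1 for m in months]
    for i in range(nlat):
        for j in range(nlon):
            if grid.mask[i, j]:
                continue
            cell = grid.values[i, j][keep][:, mcols]
            agg = cell.sum(axis=1) if stat == "sum" else cell.mean(axis=1)
            cell_series = pd.Series(agg, index=years[keep])
            pair = pd.concat([ch, cell_series], axis=1, keys=["y", "x"]).dropna()
            if len(pair) < min_overlap:
                continue
            if np.ptp(pair["x"].to_numpy()) == 0:
                continue
            res = pearsonr(pair["y"], pair["x"])
            r[i, j], p[i, j] = res.statistic, res.pvalue
            sig[i, j] = res.pvalue < alpha
    return SpatialCorrField(
        latitudes=grid.latitudes,
        longitudes=grid.longitudes,
        r=r,
        p=p,
        significant=sig,
        alpha=alpha,
        label=f"{grid.variable} {'+'.join(str(m) for m in months)} ({stat})",
    )
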