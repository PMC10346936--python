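"""Synthetic ring-width and climate generators with known ground truth.

The ring-width model is multiplicative (log-additive), matching the
assumption behind quotient detrending:

    w[i, t] = A * exp(-k * age[i, t])
              * exp(beta_t * z_t + c_t + e[i, t])
              * pointer_factor[t]

where ``z_t`` is the standardized seasonal climate aggregate the stand
responds to (e.g. June-August precipitation), ``c_t`` is a stand-level
AR(1) disturbance shared by all trees (without it, averaging many trees
would drive the chronology-signal correlation to 1 regardless of the
per-tree noise), ``e[i, t]`` are independent per-tree AR(1) deviations,
and ``pointer_factor`` plants extreme years.  Widths are rounded to
0.01 mm, like measured data.

Climate is generated with a sinusoidal temperature seasonality plus
Gaussian noise and gamma-distributed monthly precipitation whose
warm-season (April-September) share is configurable.  A gridded
counterpart mixes the base series with independent cell noise whose
weight decays with distance from a focal cell.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ringclim.core import ClimateTable, GriddedClimate, RingWidthSeries, RingWidthSet

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "gen_climate",
    "gen_ring_widths",
    "gen_gridded",
]

_WARM_MONTHS = (4, 5, 6, 7, 8, 9)


def gen_climate(
    n_years: int,
    seed: int | None = None,
    first_year: int = 1921,
    latitude: float = 45.6,
    mean_temperature: float = 10.5,
    temperature_amplitude: float = 10.0,
    temperature_noise_sd: float = 1.2,
    annual_precipitation: float = 900.0,
    warm_season_share: float = 0.55,
    precipitation_cv: float = 0.45,
    site_id: str = "SYN",
) -> ClimateTable:
    """Monthly climate with sinusoidal temperature and gamma precipitation.

    ``warm_season_share`` sets the expected fraction of annual
    precipitation falling April-September (continental regimes exceed
    0.5, maritime ones fall below).  ``precipitation_cv`` is the
    coefficient of variation of each monthly total; 0 returns the exact
    monthly means.  Temperature noise of 0 returns the exact seasonal
    sinusoid.
    """
    if n_years < 2:
        raise ValueError("need at least 2 years of climate")
    if not 0.0 <= warm_season_share <= 1.0:
        raise ValueError("warm_season_share must be within [0, 1]")
    if temperature_noise_sd < 0 or precipitation_cv < 0:
        raise ValueError("noise parameters must be >= 0")
    rng = np.random.default_rng(seed)
    years = np.arange(first_year, first_year + n_years)
    months = np.arange(1, 13)

    seasonal = mean_temperature - temperature_amplitude * np.cos(2 * np.pi * (months - 1) / 12.0)
    temp = np.tile(seasonal, (n_years, 1))
    if temperature_noise_sd > 0:
        temp = temp + rng.normal(0.0, temperature_noise_sd, size=(n_years, 12))

    p_mean = np.empty(12)
    warm = np.isin(months, _WARM_MONTHS)
    p_mean[warm] = warm_season_share * annual_precipitation / warm.sum()
    p_mean[~warm] = (1.0 - warm_season_share) * annual_precipitation / (~warm).sum()
    if np.any(p_mean < 0):
        raise ValueError("negative monthly mean precipitation")
    if precipitation_cv > 0:
        shape = 1.0 / precipitation_cv**2
        prec = rng.gamma(shape, p_mean[None, :] / shape, size=(n_years, 12))
    else:
        prec = np.broadcast_to(p_mean, (n_years, 12)).copy()

    idx = pd.Index(years, name="year")
    return ClimateTable(
        temperature=pd.DataFrame(temp, index=idx, columns=months),
        precipitation=pd.DataFrame(prec, index=idx, columns=months),
        latitude=latitude,
        site_id=site_id,
    )


@dataclass
class SyntheticParams:
    """Knobs of the ring-width generator (see module docstring for the model)."""

    n_trees: int = 80
    n_years: int = 100
    age_trend_amplitude: float = 3.0      # A, mm
    age_trend_decay: float = 0.01         # k, per year
    climate_sensitivity: float = 0.15     # beta, per standardized climate unit
    signal_months: tuple[int, ...] = (6, 7, 8)
    signal_variable: str = "precipitation"
    ar_coefficient: float = 0.5           # phi of both noise processes
    noise_sd: float = 0.45                # per-tree marginal sd (log scale)
    common_noise_sd: float = 0.2          # stand-level marginal sd (log scale)
    pointer_year_map: dict[int, float] = field(default_factory=dict)
    germination_span: tuple[int, int] = (-60, 20)  # germ year offsets vs window start
    signal_window: tuple[int, int] | None = None   # years in which beta applies
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_years < 10:
            raise ValueError("n_years must be >= 10 (generator spin-up)")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|phi| must be < 1")
        if self.noise_sd < 0 or self.common_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if any(f <= 0 for f in self.pointer_year_map.values()):
            raise ValueError("pointer-year factors must be > 0")
        if self.signal_variable not in ("precipitation", "temperature"):
            raise ValueError("signal_variable must be precipitation or temperature")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated stand."""

    signal: pd.Series                 # z_t, standardized seasonal aggregate
    common_noise: pd.Series           # c_t
    pointer_years: dict[int, float]   # planted year -> factor
    germination_years: dict[str, int]
    signal_label: str                 # e.g. "P Jun-Aug"
    seed: int | None

    def to_json(self, path) -> None:
        payload = {
            "signal": {int(y): float(v) for y, v in self.signal.items()},
            "common_noise": {int(y): float(v) for y, v in self.common_noise.items()},
            "pointer_years": {int(y): float(f) for y, f in self.pointer_years.items()},
            "germination_years": self.germination_years,
            "signal_label": self.signal_label,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        sig = pd.Series({int(k): v for k, v in d["signal"].items()}).sort_index()
        com = pd.Series({int(k): v for k, v in d["common_noise"].items()}).sort_index()
        return cls(
            signal=sig,
            common_noise=com,
            pointer_years={int(k): v for k, v in d["pointer_years"].items()},
            germination_years=d["germination_years"],
            signal_label=d["signal_label"],
            seed=d["seed"],
        )


def _ar1(rng: np.random.Generator, n: int, phi: float, marginal_sd: float) -> np.ndarray:
    """Stationary AR(1) path with the given marginal standard deviation."""
    if marginal_sd == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def signal_aggregate(climate: ClimateTable, params: SyntheticParams) -> pd.Series:
    """The standardized seasonal aggregate z_t the stand responds to."""
    tab = (
        climate.precipitation
        if params.signal_variable == "precipitation"
        else climate.temperature
    )
    sub = tab[list(params.signal_months)]
    agg = sub.sum(axis=1) if params.signal_variable == "precipitation" else sub.mean(axis=1)
    return (agg - agg.mean()) / agg.std(ddof=0)


def gen_ring_widths(
    params: SyntheticParams, climate: ClimateTable
) -> tuple[RingWidthSet, SyntheticTruth]:
    """Generate a stand of ring-width series responding to the climate.

    The simulation covers the last ``n_years`` of the climate record.
    Germination years are staggered (uniform over ``germination_span``
    relative to the window start) so sample depth varies over time, as
    in real stands; trees germinating inside the window start later.
    """
    years_all = climate.years
    if len(years_all) < params.n_years:
        raise ValueError(
            f"climate covers {len(years_all)} years; {params.n_years} required"
        )
    years = years_all[-params.n_years :]
    y0 = int(years[0])
    rng = np.random.default_rng(params.seed)

    z = signal_aggregate(climate, params).loc[years[0] :]
    beta_t = np.full(params.n_years, params.climate_sensitivity)
    if params.signal_window is not None:
        w0, w1 = params.signal_window
        inside = (years >= w0) & (years <= w1)
        beta_t = np.where(inside, params.climate_sensitivity, 0.0)
    common = _ar1(rng, params.n_years, params.ar_coefficient, params.common_noise_sd)

    factor = np.ones(params.n_years)
    for year, f in params.pointer_year_map.items():
        if not y0 <= year <= int(years[-1]):
            raise ValueError(f"pointer year {year} outside the simulated window")
        factor[year - y0] = f

    lo, hi = params.germination_span
    germ_offsets = rng.integers(lo, hi + 1, size=params.n_trees)
    series: list[RingWidthSeries] = []
    germination: dict[str, int] = {}
    common_part = beta_t * z.to_numpy() + common
    for i in range(params.n_trees):
        sid = f"SYN{i + 1:03d}"
        germ = y0 + int(germ_offsets[i])
        start = max(y0, germ + 1)
        t_slice = slice(start - y0, params.n_years)
        ages = np.arange(start, int(years[-1]) + 1) - germ
        e = _ar1(rng, len(ages), params.ar_coefficient, params.noise_sd)
        w = (
            params.age_trend_amplitude
            * np.exp(-params.age_trend_decay * ages)
            * np.exp(common_part[t_slice] + e)
            * factor[t_slice]
        )
        w = np.round(w, 2)
        series.append(
            RingWidthSeries(series_id=sid, first_year=start, widths=w, precision=0.01)
        )
        germination[sid] = germ
    rwset = RingWidthSet(series=series, plot_id="SYN", region_label="synthetic")
    mons = "".join(
        "JFMAMJJASOND"[m - 1] for m in params.signal_months
    )
    truth = SyntheticTruth(
        signal=z,
        common_noise=pd.Series(common, index=years),
        pointer_years=dict(params.pointer_year_map),
        germination_years=germination,
        signal_label=f"{'P' if params.signal_variable == 'precipitation' else 'T'} {mons}",
        seed=params.seed,
    )
    return rwset, truth


def gen_gridded(
    base: ClimateTable,
    shape: tuple[int, int] = (9, 9),
    decay_length: float = 3.0,
    seed: int | None = None,
    variable: str = "precipitation",
    focal: tuple[int, int] | None = None,
    lat0: float = 44.0,
    lon0: float = 14.0,
    cell_deg: float = 0.25,
    mask: np.ndarray | None = None,
) -> GriddedClimate:
    """Gridded field correlated with a base site series.

    Each cell's monthly anomaly is ``a * z + sqrt(1 - a^2) * eta`` where
    ``z`` is the base site's standardized anomaly, ``eta`` is
    independent cell noise, and the mixing weight
    ``a = exp(-d / decay_length)`` decays with the cell's distance ``d``
    (in cell units) from the focal cell, so the expected correlation
    with the base series equals ``a`` (1 at the focal cell).
    Precipitation cells are clipped at 0.
    """
    if decay_length <= 0:
        raise ValueError("decay_length must be > 0")
    nlat, nlon = shape
    if focal is None:
        focal = (nlat // 2, nlon // 2)
    rng = np.random.default_rng(seed)
    tab = base.precipitation if variable == "precipitation" else base.temperature
    vals = tab.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    zbase = (vals - mu) / sd

    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    dist = np.hypot(ii - focal[0], jj - focal[1])
    a = np.exp(-dist / decay_length)

    eta = rng.normal(size=(nlat, nlon, *vals.shape))
    mixed = (
        a[:, :, None, None] * zbase[None, None]
        + np.sqrt(1.0 - a[:, :, None, None] ** 2) * eta
    )
    out = mu[None, None, None, :] + sd[None, None, None, :] * mixed
    if variable == "precipitation":
        out = np.maximum(out, 0.0)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        out[mask] = np.nan
    lats = lat0 + cell_deg * np.arange(nlat)
    lons = lon0 + cell_deg * np.arange(nlon)
    return GriddedClimate(
        latitudes=lats,
        longitudes=lons,
        years=base.years,
        values=out,
        variable=variable,
    )
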