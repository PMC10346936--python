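"""Drought index (SPEI) and percentile anomaly classification.

SPEI follows the original formulation: the monthly climatic water
balance D = P - PET (PET by Thornthwaite's temperature method) is summed
over a k-month window ending in each month, a 3-parameter log-logistic
distribution is fitted per calendar month by unbiased probability-
weighted moments over a calibration period, and the fitted cumulative
probabilities are mapped through the standard-normal quantile.  Within
the calibration period each calendar month therefore has mean ~ 0 and
standard deviation ~ 1.

Anomaly classification ranks a value against a reference period
(default 1961-1990) with the Weibull plotting position m/(n+1) and bins
the percentile into seven classes from "extremely dry"/"extremely cold"
(< 2) to "extremely wet"/"extremely warm" (> 98).  High temperature
percentiles are warm; high precipitation percentiles are wet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

from ringclim.core import ClimateTable

__all__ = [
    "thornthwaite_pet",
    "SPEISeries",
    "spei",
    "percentile_classify",
    "classify_percentile",
    "AnomalyClassification",
    "anomaly_table",
]

#: mid-month day of year, used for the day-length correction
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
_DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def day_length_hours(latitude: float, month: int) -> float:
    """Mean day length (hours) for a month at a latitude, from solar declination."""
    doy = _MID_MONTH_DOY[month - 1]
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    phi = np.deg2rad(latitude)
    cos_omega = -np.tan(phi) * np.tan(decl)
    omega = np.arccos(np.clip(cos_omega, -1.0, 1.0))
    return float(24.0 / np.pi * omega)


def thornthwaite_pet(climate: ClimateTable) -> pd.DataFrame:
    """Monthly potential evapotranspiration (mm) by Thornthwaite's method.

    Per year: heat index I = sum over months with T > 0 of (T/5)^1.514;
    exponent a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239;
    PET_m = 16 (10 T_m / I)^a, corrected by day length and month length
    ((N/12) * (days/30)).  Months with mean temperature <= 0 degC have
    PET 0.  Returns a year x month (1..12) DataFrame.
    """
    T = climate.temperature.to_numpy(dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperatures must be finite")
    pos = T > 0.0
    I = np.where(pos, (np.maximum(T, 0.0) / 5.0) ** 1.514, 0.0).sum(axis=1)
    if np.all(I == 0.0):
        warnings.warn("all months at or below 0 degC: PET is zero everywhere", stacklevel=2)
    a = 6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239
    K = np.array(
        [
            day_length_hours(climate.latitude, m) / 12.0 * _DAYS_IN_MONTH[m - 1] / 30.0
            for m in range(1, 13)
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * T / I[:, None]) ** a[:, None] * K[None, :]
    pet = np.where(pos & (I[:, None] > 0), pet, 0.0)
    return pd.DataFrame(pet, index=climate.temperature.index, columns=range(1, 13))


# ---------------------------------------------------------------------------
# log-logistic fit by unbiased probability-weighted moments


def _unbiased_pwm(x: np.ndarray, r: int) -> float:
    """Unbiased estimator w_r of the probability-weighted moment
    alpha_r = E[X (1-F(X))^r], computed on the ascending order sample."""
    n = len(x)
    xs = np.sort(x)
    i = np.arange(1, n + 1, dtype=float)
    w = np.ones(n)
    for j in range(1, r + 1):
        w *= (n - i - j + 1) / (n - j)
    return float(np.mean(w * xs))


def fit_log_logistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Fit a 3-parameter log-logistic distribution by unbiased PWMs.

    Returns (alpha, beta, gamma0) = (scale, shape, origin) with CDF
    ``F(x) = [1 + (alpha / (x - gamma0))^beta]^(-1)``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 values to fit the log-logistic")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    w0 = _unbiased_pwm(x, 0)
    w1 = _unbiased_pwm(x, 1)
    w2 = _unbiased_pwm(x, 2)
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0:
        raise ValueError("PWM fit failed (degenerate moments)")
    beta = (2.0 * w1 - w0) / denom
    if not np.isfinite(beta) or abs(beta) <= 1.0:
        raise ValueError(f"log-logistic shape {beta:.3g} out of range (needs |beta| > 1)")
    g1g2 = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g1g2
    gamma0 = w0 - alpha * g1g2
    if alpha == 0:
        raise ValueError("log-logistic scale must be nonzero")
    return float(alpha), float(beta), float(gamma0)


def _log_logistic_cdf(x: np.ndarray, alpha: float, beta: float, gamma0: float) -> np.ndarray:
    """CDF ``F(x) = [1 + (alpha/(x - gamma0))^beta]^(-1)``.

    A negative (alpha, beta) pair is the reflected distribution that the
    PWM solution yields for left-skewed samples; the CDF is increasing
    in both cases.  Outside the support (ratio <= 0) F is the adjacent
    limit: 0 below a right-skewed support, 1 above a left-skewed one.
    """
    z = x - gamma0
    out = np.empty_like(x, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ratio = alpha / z
        inside = ratio > 0
        out[inside] = 1.0 / (1.0 + ratio[inside] ** beta)
    out[~inside] = 0.0 if beta > 0 else 1.0
    return out


@dataclass
class SPEISeries:
    """SPEI at scale k with its water balance and fitted parameters."""

    scale: int
    values: pd.DataFrame                # year x month (1..12); first k-1 months NaN
    water_balance: pd.DataFrame         # rolling k-month sums of D = P - PET
    params: dict[int, tuple[float, float, float]]  # month -> (alpha, beta, gamma0)
    calibration: tuple[int, int]
    monthly_d: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def month_series(self, month: int) -> pd.Series:
        """One calendar month across years."""
        return self.values[month]

    def stacked(self) -> pd.Series:
        out = self.values.stack()
        out.index.names = ["year", "month"]
        return out


def spei(
    climate: ClimateTable,
    k: int = 3,
    calibration: tuple[int, int] | None = None,
    pet: pd.DataFrame | None = None,
    clip_probability: float = 1e-6,
) -> SPEISeries:
    """Standardized Precipitation-Evapotranspiration Index at scale k months.

    Parameters
    ----------
    climate
        Monthly temperature and precipitation.
    k
        Aggregation scale in months (3 and 6 are the usual choices).
    calibration
        (first, last) year of the fitting period; defaults to the full
        record.  Values outside it are standardized with the calibration
        parameters.
    pet
        Precomputed PET (year x month, mm); defaults to Thornthwaite.
    clip_probability
        Fitted probabilities are clipped to [p, 1-p] before the normal
        quantile, bounding |SPEI| at ~4.75 and avoiding infinities.
    """
    if k < 1:
        raise ValueError("scale k must be >= 1")
    if pet is None:
        pet = thornthwaite_pet(climate)
    years = climate.temperature.index
    if calibration is None:
        calibration = (int(years[0]), int(years[-1]))
    c0, c1 = int(calibration[0]), int(calibration[1])
    if c0 < years[0] or c1 > years[-1] or c1 < c0:
        raise ValueError("calibration period must lie inside the data years")

    d_monthly = climate.precipitation - pet
    stack = d_monthly.stack()
    stack.index.names = ["year", "month"]
    dk = stack.rolling(k).sum()  # k-month sum ending at (year, month)
    dk_tab = dk.unstack()

    values = pd.DataFrame(np.nan, index=years, columns=range(1, 13))
    params: dict[int, tuple[float, float, float]] = {}
    for m in range(1, 13):
        col = dk_tab[m].dropna()
        cal = col[(col.index >= c0) & (col.index <= c1)]
        if len(cal) < 4:
            raise ValueError(f"calendar month {m}: too few calibration values")
        if np.ptp(cal.to_numpy()) == 0:
            raise ValueError(f"calendar month {m}: degenerate water-balance variance")
        try:
            alpha, beta, gamma0 = fit_log_logistic_pwm(cal.to_numpy())
        except ValueError as exc:
            raise ValueError(f"calendar month {m}: {exc}") from exc
        params[m] = (alpha, beta, gamma0)
        F = _log_logistic_cdf(col.to_numpy(), alpha, beta, gamma0)
        F = np.clip(F, clip_probability, 1.0 - clip_probability)
        values.loc[col.index, m] = norm.ppf(F)
    return SPEISeries(
        scale=k,
        values=values,
        water_balance=dk_tab,
        params=params,
        calibration=(c0, c1),
        monthly_d=d_monthly,
    )


# ---------------------------------------------------------------------------
# percentile anomaly classification

#: class bins over [0, 100]; (low, high, dry/cold label, wet/warm label)
_CLASS_BINS = [
    (0.0, 2.0, "extremely"),
    (2.0, 9.0, "very"),
    (9.0, 25.0, ""),
    (25.0, 75.0, "normal"),
    (75.0, 91.0, ""),
    (91.0, 98.0, "very"),
    (98.0, 100.0, "extremely"),
]


def classify_percentile(p: float, variable: str) -> str:
    """Map a percentile (0-100) to its anomaly class.

    Bins: <2, [2,9), [9,25), [25,75], (75,91], (91,98], >98 — exhaustive
    and mutually exclusive, with both endpoints of the normal band
    counted as normal.  Low percentiles are dry (precipitation) or cold
    (temperature); high percentiles wet or warm.
    """
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile {p} outside [0, 100]")
    if variable == "precipitation":
        low, high = "dry", "wet"
    elif variable == "temperature":
        low, high = "cold", "warm"
    else:
        raise ValueError(f"unknown variable {variable!r}")
    if 25.0 <= p <= 75.0:
        return "normal"
    if p < 25.0:
        word = "extremely" if p < 2.0 else ("very" if p < 9.0 else "")
        base = low
    else:
        word = "extremely" if p > 98.0 else ("very" if p > 91.0 else "")
        base = high
    return f"{word} {base}".strip()


def percentile_classify(
    values: pd.Series,
    reference: pd.Series,
    variable: str,
) -> pd.DataFrame:
    """Percentile (Weibull plotting position) and class for each value.

    The percentile of a value is ``100 * m / (n + 1)`` where m counts
    reference values less than or equal to it and n is the reference
    size.
    """
    if len(values) == 0:
        raise ValueError("empty value series")
    ref = np.sort(reference.to_numpy(dtype=float))
    n = len(ref)
    if n == 0:
        raise ValueError("empty reference")
    v = values.to_numpy(dtype=float)
    m = np.searchsorted(ref, v, side="right")
    pct = 100.0 * m / (n + 1.0)
    labels = [classify_percentile(p, variable) for p in pct]
    return pd.DataFrame(
        {"value": v, "percentile": pct, "label": labels}, index=values.index
    )


@dataclass
class AnomalyClassification:
    """Monthly + annual percentile classification for one variable."""

    variable: str
    reference_period: tuple[int, int]
    percentile: pd.DataFrame   # year x (1..12, "annual")
    label: pd.DataFrame        # same shape, class strings


def anomaly_table(
    climate: ClimateTable,
    variable: str,
    reference_period: tuple[int, int] = (1961, 1990),
) -> AnomalyClassification:
    """Classify every month and year of a climate record against a
    reference period (annual value: mean temperature or total
    precipitation)."""
    tab = climate.temperature if variable == "temperature" else climate.precipitation
    r0, r1 = reference_period
    ref_tab = tab.loc[(tab.index >= r0) & (tab.index <= r1)]
    if ref_tab.empty:
        raise ValueError("reference period outside the climate record")
    pct = pd.DataFrame(index=tab.index, columns=[*range(1, 13), "annual"], dtype=float)
    lab = pd.DataFrame(index=tab.index, columns=[*range(1, 13), "annual"], dtype=object)
    for m in range(1, 13):
        res = percentile_classify(tab[m], ref_tab[m], variable)
        pct[m] = res["percentile"]
        lab[m] = res["label"]
    annual = tab.mean(axis=1) if variable == "temperature" else tab.sum(axis=1)
    annual_ref = annual.loc[(annual.index >= r0) & (annual.index <= r1)]
    res = percentile_classify(annual, annual_ref, variable)
    pct["annual"] = res["percentile"]
    lab["annual"] = res["label"]
    return AnomalyClassification(
        variable=variable,
        reference_period=(int(r0), int(r1)),
        percentile=pct,
        label=lab,
    )
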