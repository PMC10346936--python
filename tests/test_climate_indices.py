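import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisk, norm, skew

from ringclim.climate_indices import (
    anomaly_table,
    classify_percentile,
    fit_log_logistic_pwm,
    percentile_classify,
    spei,
    thornthwaite_pet,
)
from ringclim.core import ClimateTable
from ringclim.synthetic import gen_climate


def _make_climate(temp_by_month, precip_by_month, n_years=3, latitude=45.0, first=2000):
    years = pd.Index(range(first, first + n_years))
    t = pd.DataFrame([temp_by_month] * n_years, index=years, columns=range(1, 13))
    p = pd.DataFrame([precip_by_month] * n_years, index=years, columns=range(1, 13))
    return ClimateTable(temperature=t, precipitation=p, latitude=latitude)


# ---------------------------------------------------------------------------
# Thornthwaite PET


def _thornthwaite_oracle(temps, latitude):
    """Step-by-step scalar evaluation of the Thornthwaite formulas."""
    mid_doy = [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]
    days = [31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    I = sum((t / 5.0) ** 1.514 for t in temps if t > 0)
    a = 6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239
    out = []
    for m, t in enumerate(temps):
        if t <= 0 or I == 0:
            out.append(0.0)
            continue
        decl = 0.409 * math.sin(2 * math.pi * mid_doy[m] / 365 - 1.39)
        cos_om = -math.tan(math.radians(latitude)) * math.tan(decl)
        om = math.acos(min(1.0, max(-1.0, cos_om)))
        N = 24 / math.pi * om
        K = (N / 12.0) * (days[m] / 30.0)
        out.append(16.0 * (10.0 * t / I) ** a * K)
    return out


def test_pet_zero_when_freezing():
    clim = _make_climate([-5.0] * 12, [50.0] * 12)
    with pytest.warns(UserWarning, match="PET is zero"):
        pet = thornthwaite_pet(clim)
    assert (pet.to_numpy() == 0).all()


def test_pet_matches_independent_formula_evaluation():
    temps = [20.0] * 12
    clim = _make_climate(temps, [60.0] * 12, latitude=45.0)
    pet = thornthwaite_pet(clim)
    oracle = _thornthwaite_oracle(temps, 45.0)
    assert pet.iloc[0].to_numpy() == pytest.approx(oracle, rel=1e-10)
    # and a seasonal profile with freezing months
    temps2 = [-2.0, 0.0, 4.0, 9.0, 14.0, 18.0, 21.0, 20.0, 15.0, 10.0, 5.0, 0.5]
    clim2 = _make_climate(temps2, [60.0] * 12, latitude=46.0)
    pet2 = thornthwaite_pet(clim2)
    assert pet2.iloc[0].to_numpy() == pytest.approx(
        _thornthwaite_oracle(temps2, 46.0), rel=1e-10
    )
    assert pet2.iloc[0, 0] == 0.0  # January below zero


def test_pet_deterministic_across_identical_sites():
    temps = [10.0] * 12
    a = thornthwaite_pet(_make_climate(temps, [50.0] * 12, latitude=45.0))
    b = thornthwaite_pet(_make_climate(temps, [90.0] * 12, latitude=45.0))
    pd.testing.assert_frame_equal(a, b)  # PET depends on temperature only


# ---------------------------------------------------------------------------
# log-logistic PWM fit


@pytest.mark.parametrize("alpha,beta,gamma0", [(50.0, 4.0, -120.0), (10.0, 2.5, 3.0)])
def test_log_logistic_fit_recovers_known_parameters(alpha, beta, gamma0):
    x = fisk.rvs(beta, loc=gamma0, scale=alpha, size=20000, random_state=42)
    ah, bh, gh = fit_log_logistic_pwm(x)
    assert ah == pytest.approx(alpha, rel=0.05)
    assert bh == pytest.approx(beta, rel=0.05)
    assert gh == pytest.approx(gamma0, abs=0.05 * alpha)


def test_log_logistic_fit_handles_left_skew():
    """Left-skewed samples yield the reflected (negative-shape) solution."""
    x = -fisk.rvs(3.0, loc=0.0, scale=40.0, size=5000, random_state=7)
    assert skew(x) < -0.2
    ah, bh, gh = fit_log_logistic_pwm(x)
    assert bh < -1.0


def test_log_logistic_fit_rejects_degenerate():
    with pytest.raises(ValueError):
        fit_log_logistic_pwm(np.full(30, 5.0))


# ---------------------------------------------------------------------------
# SPEI


@pytest.fixture(scope="module")
def calib_climate():
    return gen_climate(70, seed=77, warm_season_share=0.6)


def test_spei_calibration_standardization(calib_climate):
    res = spei(calib_climate, k=3, calibration=(1931, 1990))
    cal = res.values.loc[1931:1990]
    for m in range(1, 13):
        vals = cal[m].dropna()
        assert abs(vals.mean()) < 0.05, f"month {m}"
        assert abs(vals.std(ddof=0) - 1) < 0.05, f"month {m}"


def test_spei_first_months_undefined(calib_climate):
    res = spei(calib_climate, k=3)
    first = res.values.iloc[0]
    assert first[[1, 2]].isna().all()
    assert np.isfinite(first[3])


def test_spei_monotone_in_water_balance(calib_climate):
    """A wetter month (larger D) maps to a strictly larger SPEI."""
    res = spei(calib_climate, k=1, calibration=(1931, 1990))
    for m in (2, 8):
        d = res.water_balance[m].dropna()
        s = res.values[m].reindex(d.index)
        order = d.sort_values().index
        assert s.loc[order].is_monotonic_increasing


def test_spei_translation_equivariance(calib_climate):
    """Shifting every D by a constant refits to identical SPEI values."""
    pet = thornthwaite_pet(calib_climate)
    res0 = spei(calib_climate, k=1, pet=pet, calibration=(1931, 1990))
    res1 = spei(calib_climate, k=1, pet=pet - 25.0, calibration=(1931, 1990))
    pd.testing.assert_frame_equal(res0.values, res1.values, atol=1e-8, rtol=0)


def test_spei_planted_dry_august_is_minimum(calib_climate):
    clim = calib_climate
    prec = clim.precipitation.copy()
    year = 1975
    prec.loc[year, [6, 7, 8]] *= 0.2  # severe summer drought
    dry = ClimateTable(
        temperature=clim.temperature, precipitation=prec, latitude=clim.latitude
    )
    res = spei(dry, k=3, calibration=(1931, 1990))
    august = res.values[8].dropna()
    assert august.idxmin() == year


def test_spei_rejects_bad_inputs(calib_climate):
    with pytest.raises(ValueError):
        spei(calib_climate, k=0)
    with pytest.raises(ValueError):
        spei(calib_climate, calibration=(1800, 1990))


def test_spei_normal_scale_sanity(calib_climate):
    """k=1 SPEI values over the calibration period look standard normal."""
    res = spei(calib_climate, k=1)
    vals = res.values.to_numpy().ravel()
    vals = vals[np.isfinite(vals)]
    assert abs(skew(vals)) < 0.3
    assert np.nanmax(np.abs(vals)) < norm.ppf(1 - 1e-7)


# ---------------------------------------------------------------------------
# percentile classification


def _percentile_oracle(value, reference):
    m = sum(1 for r in reference if r <= value)
    return 100.0 * m / (len(reference) + 1)


def test_percentile_hand_cases():
    ref = pd.Series([10.0, 20.0, 30.0])
    out = percentile_classify(pd.Series([20.0]), ref, "precipitation")
    assert out["percentile"].iloc[0] == pytest.approx(50.0)
    assert out["label"].iloc[0] == "normal"
    below = percentile_classify(pd.Series([1.0]), ref, "precipitation")
    assert below["percentile"].iloc[0] < 2
    assert below["label"].iloc[0] == "extremely dry"


def test_percentile_median_of_reference_is_normal(rng):
    ref = pd.Series(rng.normal(100, 20, size=30))
    out = percentile_classify(pd.Series([ref.median()]), ref, "precipitation")
    assert out["label"].iloc[0] == "normal"


def test_percentile_matches_brute_force(rng):
    ref = pd.Series(rng.normal(50, 10, size=29))
    vals = pd.Series(rng.normal(50, 15, size=200))
    out = percentile_classify(vals, ref, "temperature")
    for v, p in zip(vals, out["percentile"]):
        assert p == pytest.approx(_percentile_oracle(v, ref.tolist()), abs=1e-9)


@pytest.mark.parametrize(
    "p,variable,label",
    [
        (0.0, "precipitation", "extremely dry"),
        (2.0, "precipitation", "very dry"),
        (9.0, "precipitation", "dry"),
        (25.0, "precipitation", "normal"),
        (75.0, "precipitation", "normal"),
        (91.0, "precipitation", "wet"),
        (98.0, "precipitation", "very wet"),
        (98.1, "precipitation", "extremely wet"),
        (1.0, "temperature", "extremely cold"),
        (99.0, "temperature", "extremely warm"),
    ],
)
def test_class_boundaries_deterministic(p, variable, label):
    assert classify_percentile(p, variable) == label


def test_class_bins_exhaustive_and_exclusive():
    grid = np.linspace(0, 100, 10001)
    labels = [classify_percentile(p, "precipitation") for p in grid]
    assert all(labels)  # every percentile maps to exactly one class
    # ordered classes appear in contiguous blocks
    changes = [l2 for l1, l2 in zip(labels, labels[1:]) if l1 != l2]
    assert changes == ["very dry", "dry", "normal", "wet", "very wet", "extremely wet"]


def test_anomaly_table_hot_dry_year(calib_climate):
    clim = calib_climate
    temp = clim.temperature.copy()
    prec = clim.precipitation.copy()
    temp.loc[1985] += 6.0
    prec.loc[1985] *= 0.3
    mod = ClimateTable(temperature=temp, precipitation=prec, latitude=clim.latitude)
    t_cls = anomaly_table(mod, "temperature", (1931, 1980))
    p_cls = anomaly_table(mod, "precipitation", (1931, 1980))
    assert t_cls.percentile.loc[1985, "annual"] > 98       # hottest on record
    assert t_cls.label.loc[1985, "annual"] == "extremely warm"
    assert p_cls.percentile.loc[1985, "annual"] < 2
    assert p_cls.label.loc[1985, "annual"] == "extremely dry"
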