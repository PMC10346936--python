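import numpy as np
import pandas as pd
import pytest

from ringclim.chronology import (
    biweight_mean,
    build_chronology,
    compose_regional,
    detrend,
    eps_wigley,
    fit_spline,
    prewhiten,
    running_signal_stats,
)
from ringclim.core import RingWidthSeries, RingWidthSet
from ringclim.synthetic import SyntheticParams, gen_ring_widths

from conftest import year_series


# ---------------------------------------------------------------------------
# spline + detrend


def test_spline_reproduces_constant_series():
    s = RingWidthSeries("C", 1900, np.full(60, 2.0))
    fit = fit_spline(s)
    assert fit.fitted == pytest.approx(2.0, abs=1e-9)


def test_spline_rejects_short_series():
    with pytest.raises(ValueError, match="at least"):
        fit_spline(RingWidthSeries("S", 1900, np.full(5, 1.0)))


def test_spline_response_monotone_in_wavelength():
    """Longer wavelengths are retained more by the fitted growth curve."""
    n = 120
    t = np.arange(n, dtype=float)

    def response(P):
        w = 2.0 + 0.3 * np.sin(2 * np.pi * t / P)
        fit = fit_spline(RingWidthSeries("M", 1900, w))
        B = np.column_stack([np.sin(2 * np.pi * t / P), np.cos(2 * np.pi * t / P)])
        coef, *_ = np.linalg.lstsq(B, fit.fitted - fit.fitted.mean(), rcond=None)
        return float(np.hypot(*coef)) / 0.3

    resp = [response(P) for P in (n / 10, n / 4, n / 2, 0.67 * n)]
    assert np.all(np.diff(resp) > 0)


def test_detrend_quotient_arithmetic():
    s = RingWidthSeries("Q", 2000, np.array([1.0, 2.0] + [2.0] * 10))
    fit = fit_spline(s, min_length=5)
    fit.fitted[:] = 2.0
    idx = detrend(s, fit)
    assert idx.iloc[0] == 0.5
    assert idx.iloc[1] == 1.0


def test_detrend_keeps_missing_rings_as_zero():
    widths = np.full(30, 2.0)
    widths[10] = 0.0
    s = RingWidthSeries("Z", 2000, widths)
    idx = detrend(s, fit_spline(s))
    assert idx.iloc[10] == 0.0
    assert (idx.drop(idx.index[10]) > 0).all()


def test_detrended_synthetic_mean_near_one(base_climate):
    params = SyntheticParams(n_trees=8, n_years=100, seed=41, germination_span=(-40, -1))
    rwset, _ = gen_ring_widths(params, base_climate)
    means = [detrend(s, fit_spline(s)).mean() for s in rwset.series]
    assert np.mean(means) == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# prewhitening


def test_prewhiten_white_noise_mostly_selects_order_zero():
    rng = np.random.default_rng(51)
    orders = []
    for _ in range(40):
        s = year_series(1 + 0.1 * rng.normal(size=120))
        _, model = prewhiten(s)
        orders.append(model.order)
    assert np.mean(np.array(orders) == 0) > 0.5


def test_prewhiten_removes_ar1_autocorrelation():
    rng = np.random.default_rng(52)
    x = np.empty(300)
    x[0] = 0.0
    e = rng.normal(size=300)
    for t in range(1, 300):
        x[t] = 0.7 * x[t - 1] + e[t]
    res, model = prewhiten(year_series(1 + 0.1 * x, first_year=1700))
    r = res.dropna().to_numpy()
    rho1 = np.corrcoef(r[1:], r[:-1])[0, 1]
    assert abs(rho1) < 0.1
    assert model.order >= 1
    assert res.dropna().mean() == pytest.approx(1.0, abs=1e-9)


def test_prewhiten_reduces_high_autocorrelation():
    """Residual lag-1 autocorrelation is below the input's when it was strong."""
    rng = np.random.default_rng(53)
    for _ in range(10):
        phi = rng.uniform(0.4, 0.8)
        x = np.empty(200)
        x[0] = 0.0
        e = rng.normal(size=200)
        for t in range(1, 200):
            x[t] = phi * x[t - 1] + e[t]
        s = year_series(1 + 0.1 * x, first_year=1800)
        rho_in = np.corrcoef(x[1:], x[:-1])[0, 1]
        if abs(rho_in) <= 0.3:
            continue
        res, _ = prewhiten(s)
        r = res.dropna().to_numpy()
        rho_out = np.corrcoef(r[1:], r[:-1])[0, 1]
        assert abs(rho_out) < abs(rho_in)


# ---------------------------------------------------------------------------
# biweight mean


def _biweight_oracle(values, c=9.0, n_iter=500):
    """Independent brute-force fixed-point iteration (no early stopping)."""
    v = np.asarray(values, dtype=float)
    m = np.median(v)
    mad = np.median(np.abs(v - m))
    if mad == 0:
        return m
    for _ in range(n_iter):
        u = (v - m) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        m = np.sum(w * v) / np.sum(w)
    return m


@pytest.mark.parametrize(
    "values,expected",
    [
        ([1, 1, 1, 1], 1.0),
        ([0.8, 1.0, 1.2], 1.0),
        ([5.0], 5.0),
    ],
)
def test_biweight_simple_cases(values, expected):
    assert biweight_mean(values) == pytest.approx(expected)


def test_biweight_downweights_outlier():
    # MAD = 0 here (four identical values), so the estimate stays at the median
    assert biweight_mean([1.0, 1.0, 1.0, 1.0, 5.0]) == 1.0
    # with a spread sample the outlier is pulled in only weakly
    val = biweight_mean([0.9, 1.0, 1.1, 1.05, 5.0])
    assert 1.0 < val < 1.1
    assert val == pytest.approx(_biweight_oracle([0.9, 1.0, 1.1, 1.05, 5.0]), abs=1e-6)


def test_biweight_matches_oracle_on_random_samples(rng):
    for _ in range(200):
        v = rng.normal(1.0, 0.3, size=int(rng.integers(3, 30)))
        assert biweight_mean(v) == pytest.approx(_biweight_oracle(v), abs=1e-5)


# ---------------------------------------------------------------------------
# chronology building + signal stats


def test_chronology_of_single_series_is_that_series():
    s = year_series([1.0, 1.1, 0.9, 1.2, 0.8])
    chron = build_chronology([s])
    assert np.allclose(chron.index, s.to_numpy())
    assert np.all(chron.sample_depth == 1)


def test_chronology_of_identical_series_is_either():
    s = year_series([1.0, 1.1, 0.9, 1.2])
    chron = build_chronology([s, s.rename("b")])
    assert np.allclose(chron.index, s.to_numpy())
    assert np.all(chron.sample_depth == 2)


def test_chronology_depth_counts_available_series():
    a = year_series([1.0, 1.1, 0.9], first_year=2000)
    b = year_series([1.2, 0.8], first_year=2001)
    chron = build_chronology([a, b.rename("b")])
    assert list(chron.sample_depth) == [1, 2, 2]


def test_eps_closed_form_and_limits():
    assert eps_wigley(0.5, 10) == pytest.approx(10 * 0.5 / (10 * 0.5 + 0.5), abs=1e-12)
    assert eps_wigley(0.0, 10) == 0.0
    assert eps_wigley(1.0, 10) == 1.0


def test_eps_monotone_in_n_and_rbar():
    rbars = np.linspace(0.05, 0.95, 20)
    ns = np.arange(2, 42, 2)
    grid = np.array([[eps_wigley(r, n) for n in ns] for r in rbars])
    assert np.all(np.diff(grid, axis=0) > 0)   # increasing in rbar
    assert np.all(np.diff(grid, axis=1) > 0)   # increasing in N
    assert np.all((grid >= 0) & (grid <= 1))


def test_running_stats_identical_series_give_eps_one(rng):
    base = year_series(1 + 0.1 * rng.normal(size=60), first_year=1900)
    series = [base.rename(f"s{i}") for i in range(5)]
    stats = running_signal_stats(series, window=30, overlap=15)
    assert np.allclose(stats["rbar"].dropna(), 1.0)
    assert np.allclose(stats["eps"].dropna(), 1.0)
    assert (stats["n"] == 5).all()


def test_running_stats_windows_step_by_window_minus_overlap(rng):
    series = [
        year_series(1 + 0.1 * rng.normal(size=100), first_year=1900).rename(f"s{i}")
        for i in range(4)
    ]
    stats = running_signal_stats(series, window=50, overlap=25)
    assert list(np.diff(stats.index)) == [25] * (len(stats) - 1)


def test_running_stats_needs_two_series_per_window(rng):
    a = year_series(1 + 0.1 * rng.normal(size=40), first_year=1900)
    b = year_series(1 + 0.1 * rng.normal(size=40), first_year=1970).rename("b")
    stats = running_signal_stats([a, b], window=20, overlap=0)
    # no window has both series: stats missing everywhere
    assert stats["rbar"].isna().all()


# ---------------------------------------------------------------------------
# regional pooling


def _tiny_set(plot, ids, seed):
    rng = np.random.default_rng(seed)
    return RingWidthSet(
        series=[
            RingWidthSeries(i, 1950, np.round(rng.gamma(4, 0.5, 30), 2)) for i in ids
        ],
        plot_id=plot,
    )


def test_compose_regional_merges_and_disambiguates():
    a = _tiny_set("P1", ["T01", "T02"], 1)
    b = _tiny_set("P2", ["T01", "T03"], 2)
    merged = compose_regional([a, b], region_label="reg")
    assert len(merged) == 4
    assert len(set(merged.series_ids)) == 4
    assert merged.region_label == "reg"


def test_compose_regional_many_truncation_collisions():
    """Two plots sharing 12 long ids still merge to unique 8-char ids."""
    ids = [f"SYN{i:03d}X" for i in range(12)]
    a = _tiny_set("plotA", ids, 4)
    b = _tiny_set("plotB", ids, 5)
    merged = compose_regional([a, b])
    assert len(merged) == 24
    assert len(set(merged.series_ids)) == 24
    assert all(len(sid) <= 8 for sid in merged.series_ids)


def test_compose_regional_single_plot_identity():
    a = _tiny_set("P1", ["T01", "T02"], 3)
    merged = compose_regional([a])
    assert merged.series == a.series
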