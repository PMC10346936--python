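import warnings

import numpy as np
import pandas as pd
import pytest

from ringclim.core import ClimateTable, RingWidthSeries, RingWidthSet
from ringclim.synthetic import gen_climate

# statsmodels emits harmless value warnings on short AR fits
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def base_climate() -> ClimateTable:
    """120 years of synthetic monthly climate, continental-ish regime."""
    return gen_climate(120, seed=101, warm_season_share=0.6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_ring_width_set(rng: np.random.Generator, n_series=None) -> RingWidthSet:
    """A random but valid RingWidthSet (both precision dialects)."""
    n_series = n_series or int(rng.integers(1, 6))
    series = []
    for i in range(n_series):
        n = int(rng.integers(10, 80))
        precision = [0.01, 0.001][int(rng.integers(2))]
        widths = np.round(rng.gamma(4.0, 0.5, size=n) / precision) * precision
        if rng.random() < 0.3:  # sprinkle missing rings
            widths[rng.integers(0, n, size=2)] = 0.0
        series.append(
            RingWidthSeries(
                series_id=f"T{i:02d}X{int(rng.integers(100)):02d}",
                first_year=int(rng.integers(1500, 1990)),
                widths=widths,
                precision=precision,
            )
        )
    return RingWidthSet(series=series, plot_id="RND", region_label="test")


def year_series(values, first_year=1950) -> pd.Series:
    return pd.Series(
        np.asarray(values, dtype=float),
        index=np.arange(first_year, first_year + len(values)),
    )
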