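"""Core data containers: ring-width series/sets and monthly climate tables.

Conventions
-----------
* Ring widths are stored in millimetres.  A width of exactly 0 encodes a
  missing (locally absent) ring; it is kept as data, never dropped.
* Years are calendar years (CE) and strictly consecutive within a series.
  A series with a gap in its year coverage must be split into two series.
* Monthly tables are indexed by year with integer columns 1..12
  (January..December).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: month numbers -> lower-case three-letter names used in CSV headers
MONTH_NAMES = [
    "jan", "feb", "mar", "apr", "may", "jun",
    "jul", "aug", "sep", "oct", "nov", "dec",
]
MONTH_TO_NUM = {name: i + 1 for i, name in enumerate(MONTH_NAMES)}


@dataclass
class RingWidthSeries:
    """Dated annual ring widths for one measurement series (core or tree).

    Parameters
    ----------
    series_id
        Identifier, at most 8 characters for Tucson/RWL export.
    first_year
        Calendar year of the first ring.
    widths
        Ring widths in mm; non-negative; 0 marks a missing ring.
    precision
        Measurement resolution of the source file: 0.01 mm (RWL
        sentinel 999) or 0.001 mm (sentinel -9999).
    """

    series_id: str
    first_year: int
    widths: np.ndarray
    precision: float = 0.01

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError(f"series {self.series_id!r}: widths must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(self.widths)):
            raise ValueError(f"series {self.series_id!r}: widths must be finite")
        if np.any(self.widths < 0):
            raise ValueError(f"series {self.series_id!r}: widths must be >= 0")
        if self.precision not in (0.01, 0.001):
            raise ValueError(f"series {self.series_id!r}: precision must be 0.01 or 0.001 mm")
        self.first_year = int(self.first_year)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    def to_series(self) -> pd.Series:
        """Year-indexed pandas Series of widths (mm)."""
        return pd.Series(self.widths, index=self.years, name=self.series_id)

    def __len__(self) -> int:
        return len(self.widths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingWidthSeries):
            return NotImplemented
        return (
            self.series_id == other.series_id
            and self.first_year == other.first_year
            and self.precision == other.precision
            and np.array_equal(self.widths, other.widths)
        )


@dataclass
class RingWidthSet:
    """A collection of ring-width series from one plot or region."""

    series: list[RingWidthSeries]
    plot_id: str = ""
    region_label: str = ""

    def __post_init__(self) -> None:
        if len(self.series) == 0:
            raise ValueError("a RingWidthSet needs at least one series")
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate series ids: {dupes}")

    def to_frame(self) -> pd.DataFrame:
        """Common-year table (union of year ranges); absent years are NaN."""
        return pd.concat([s.to_series() for s in self.series], axis=1).sort_index()

    @property
    def series_ids(self) -> list[str]:
        return [s.series_id for s in self.series]

    def __len__(self) -> int:
        return len(self.series)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingWidthSet):
            return NotImplemented
        return (
            self.plot_id == other.plot_id
            and self.region_label == other.region_label
            and self.series == other.series
        )


def _check_monthly(table: pd.DataFrame, what: str) -> pd.DataFrame:
    table = table.copy()
    table.columns = [int(c) for c in table.columns]
    if list(table.columns) != list(range(1, 13)):
        raise ValueError(f"{what}: expected 12 monthly columns 1..12, got {list(table.columns)}")
    table.index = table.index.astype(int)
    return table.sort_index()


@dataclass
class ClimateTable:
    """Monthly temperature (degC) and precipitation (mm) for one site.

    Both tables are year-indexed DataFrames with columns 1..12 and must
    cover exactly the same, gap-free, year range.
    """

    temperature: pd.DataFrame
    precipitation: pd.DataFrame
    latitude: float = 45.0
    site_id: str = ""

    def __post_init__(self) -> None:
        self.temperature = _check_monthly(self.temperature, "temperature")
        self.precipitation = _check_monthly(self.precipitation, "precipitation")
        if not self.temperature.index.equals(self.precipitation.index):
            raise ValueError("temperature and precipitation must share identical year coverage")
        years = self.temperature.index.to_numpy()
        if len(years) and np.any(np.diff(years) != 1):
            raise ValueError("non-consecutive years in climate table")
        if np.nanmin(self.precipitation.to_numpy()) < 0:
            raise ValueError("negative precipitation")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude out of range")

    @property
    def years(self) -> np.ndarray:
        return self.temperature.index.to_numpy()

    def subset(self, first: int, last: int) -> "ClimateTable":
        """Restrict to years ``first..last`` inclusive."""
        sel = (self.temperature.index >= first) & (self.temperature.index <= last)
        return ClimateTable(
            temperature=self.temperature.loc[sel],
            precipitation=self.precipitation.loc[sel],
            latitude=self.latitude,
            site_id=self.site_id,
        )

    def monthly_stack(self, variable: str) -> pd.Series:
        """Flatten a monthly table into a (year, month)-indexed Series."""
        tab = self.temperature if variable == "temperature" else self.precipitation
        out = tab.stack()
        out.index.names = ["year", "month"]
        return out


@dataclass
class GriddedClimate:
    """A lat x lon x (year, month) monthly climate field.

    ``values`` has shape (nlat, nlon, nyears, 12); ``mask`` is True for
    cells with no data (e.g. ocean), and such cells are all-NaN.
    """

    latitudes: np.ndarray
    longitudes: np.ndarray
    years: np.ndarray
    values: np.ndarray
    variable: str = "precipitation"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        for name, coord in (("latitudes", self.latitudes), ("longitudes", self.longitudes)):
            if coord.ndim != 1 or (len(coord) > 1 and not np.all(np.diff(coord) > 0)):
                raise ValueError(f"{name} must be a strictly increasing vector")
        expected = (len(self.latitudes), len(self.longitudes), len(self.years), 12)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.variable not in ("temperature", "precipitation", "spei"):
            raise ValueError(f"unknown variable {self.variable!r}")
        empty = np.all(np.isnan(self.values), axis=(2, 3))
        if self.mask is None:
            self.mask = empty
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != empty.shape:
                raise ValueError("mask shape must be (nlat, nlon)")
            if np.any(self.mask & ~empty) or np.any(~self.mask & empty):
                raise ValueError("mask inconsistent with missing values")

    def cell_series(self, i: int, j: int) -> pd.DataFrame:
        """Year x month DataFrame for one grid cell."""
        return pd.DataFrame(self.values[i, j], index=self.years, columns=range(1, 13))
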