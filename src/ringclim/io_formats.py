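"""Readers and writers for the pipeline's file formats.

Three formats are supported:

* **Tucson/RWL decadal** ring-width files, in both common dialects:
  units of 0.01 mm with terminal sentinel ``999``, and units of
  0.001 mm with sentinel ``-9999``.  The dialect is autodetected on
  read and chosen by each series' ``precision`` on write.
* **Climate CSV** with a fixed, documented schema: columns
  ``site_id, latitude, year, variable, jan..dec`` where ``variable``
  is ``temperature`` (degC) or ``precipitation`` (mm).
* **Gridded climate** as a NetCDF file with dimensions
  (lat, lon, year, month), read and written through xarray.

Round-tripping is exact: integers in an RWL file are reproduced
bit-for-bit by ``write_rwl(read_rwl(path))``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import xarray as xr

from ringclim.core import MONTH_NAMES, ClimateTable, GriddedClimate, RingWidthSeries, RingWidthSet

_SENTINELS = {0.01: 999, 0.001: -9999}


class RwlParseError(ValueError):
    """Raised when a Tucson/RWL file violates the decadal layout."""


def _decade_start(year: int) -> int:
    return (year // 10) * 10


def read_rwl(path: str | os.PathLike, plot_id: str = "", region_label: str = "") -> RingWidthSet:
    """Read a Tucson/RWL decadal ring-width file.

    Values are converted to mm using the dialect detected from the
    terminal sentinel of each series (999 -> 0.01 mm, -9999 -> 0.001 mm).
    A value of 0 is a missing (locally absent) ring and is preserved.
    """
    raw: dict[str, tuple[int, list[int], float]] = {}
    order: list[str] = []
    open_sid: str | None = None
    open_first: int = 0
    open_vals: list[int] = []
    open_next_decade: int | None = None

    def close_series(lineno: int) -> None:
        nonlocal open_sid, open_vals
        if open_sid is None:
            return
        if not open_vals:
            raise RwlParseError(f"line {lineno}: series {open_sid!r} has no values")
        sentinel = open_vals[-1]
        if sentinel == _SENTINELS[0.01]:
            precision = 0.01
        elif sentinel == _SENTINELS[0.001]:
            precision = 0.001
        else:
            raise RwlParseError(
                f"line {lineno}: series {open_sid!r} missing terminal sentinel (999 or -9999)"
            )
        values = open_vals[:-1]
        if not values:
            raise RwlParseError(f"line {lineno}: series {open_sid!r} contains only a sentinel")
        if open_sid in raw:
            raise RwlParseError(f"line {lineno}: duplicate series id {open_sid!r}")
        raw[open_sid] = (open_first, values, precision)
        order.append(open_sid)
        open_sid = None
        open_vals = []

    with open(path, "r", encoding="ascii") as fh:
        lines = fh.read().splitlines()

    lineno = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        sid = line[:8].strip()
        if not sid:
            raise RwlParseError(f"line {lineno}: missing series id in columns 1-8")
        tokens = line[8:].split()
        if not tokens:
            raise RwlParseError(f"line {lineno}: no decade label")
        try:
            year = int(tokens[0])
        except ValueError as exc:
            raise RwlParseError(f"line {lineno}: malformed decade label {tokens[0]!r}") from exc
        try:
            vals = [int(t) for t in tokens[1:]]
        except ValueError as exc:
            raise RwlParseError(f"line {lineno}: non-integer width field") from exc

        if sid != open_sid:
            close_series(lineno)
            open_sid = sid
            open_first = year
            open_vals = []
            open_next_decade = _decade_start(year) + 10
        else:
            if open_next_decade is None or year != open_next_decade:
                raise RwlParseError(
                    f"line {lineno}: non-consecutive decades for series {sid!r} "
                    f"(expected {open_next_decade}, got {year})"
                )
            open_next_decade += 10
        open_vals.extend(vals)
    close_series(lineno + 1)

    series = [
        RingWidthSeries(
            series_id=sid,
            first_year=first,
            widths=np.asarray(vals, dtype=float) * prec,
            precision=prec,
        )
        for sid, (first, vals, prec) in ((s, raw[s]) for s in order)
    ]
    if not series:
        raise RwlParseError(f"{path}: no series found")
    return RingWidthSet(series=series, plot_id=plot_id, region_label=region_label)


def write_rwl(rwset: RingWidthSet, path: str | os.PathLike) -> None:
    """Write a Tucson/RWL decadal file.

    Each series is laid out in decade rows (``id`` in columns 1-8, the
    decade's first data year right-aligned in columns 9-12, widths as
    right-aligned 6-character integer fields) and closed with the
    sentinel matching its ``precision``.
    """
    out_lines: list[str] = []
    for s in rwset.series:
        if len(s.series_id) > 8:
            raise ValueError(
                f"series id {s.series_id!r} exceeds 8 characters; truncate or rename "
                "(e.g. keep a plot prefix plus a tree number)"
            )
        ints = np.rint(s.widths / s.precision).astype(int)
        sentinel = _SENTINELS[s.precision]
        fields = [*(int(v) for v in ints), sentinel]
        year = s.first_year
        pos = 0
        while pos < len(fields):
            decade_end = _decade_start(year) + 10
            n_here = min(decade_end - year, len(fields) - pos)
            row = fields[pos : pos + n_here]
            out_lines.append(
                f"{s.series_id:<8}{year:>4}" + "".join(f"{v:>6}" for v in row)
            )
            pos += n_here
            year += n_here
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(out_lines) + "\n")


# ---------------------------------------------------------------------------
# climate CSV

_CLIMATE_COLS = ["site_id", "latitude", "year", "variable", *MONTH_NAMES]


def write_climate_csv(climate: ClimateTable, path: str | os.PathLike) -> None:
    """Write a ClimateTable in the fixed CSV schema (see module docstring)."""
    rows = []
    for variable, table in (
        ("temperature", climate.temperature),
        ("precipitation", climate.precipitation),
    ):
        for year, row in table.iterrows():
            rows.append(
                [climate.site_id, climate.latitude, int(year), variable, *row.to_list()]
            )
    pd.DataFrame(rows, columns=_CLIMATE_COLS).to_csv(path, index=False)


def read_climate_csv(path: str | os.PathLike) -> ClimateTable:
    """Read a ClimateTable from the fixed CSV schema; validates invariants."""
    df = pd.read_csv(path)
    missing = [c for c in _CLIMATE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    tables = {}
    for variable in ("temperature", "precipitation"):
        sub = df[df["variable"] == variable]
        if sub.empty:
            raise ValueError(f"{path}: no {variable} rows")
        tab = sub.set_index(sub["year"].astype(int))[MONTH_NAMES]
        tab.columns = range(1, 13)
        years = tab.index.to_numpy()
        if np.any(np.diff(years) != 1):
            raise ValueError(f"{path}: non-consecutive years in {variable} rows")
        tables[variable] = tab.astype(float)
    lat = float(df["latitude"].iloc[0])
    site = str(df["site_id"].iloc[0]) if not pd.isna(df["site_id"].iloc[0]) else ""
    return ClimateTable(
        temperature=tables["temperature"],
        precipitation=tables["precipitation"],
        latitude=lat,
        site_id=site,
    )


# ---------------------------------------------------------------------------
# gridded climate (NetCDF through xarray)


def write_gridded(grid: GriddedClimate, path: str | os.PathLike) -> None:
    """Write a gridded monthly field to NetCDF (dimensions lat, lon, year, month)."""
    da = xr.DataArray(
        grid.values,
        dims=("lat", "lon", "year", "month"),
        coords={
            "lat": grid.latitudes,
            "lon": grid.longitudes,
            "year": grid.years,
            "month": np.arange(1, 13),
        },
        name=grid.variable,
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_gridded(path: str | os.PathLike) -> GriddedClimate:
    """Read a gridded monthly field written by :func:`write_gridded`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        names = [n for n in ds.data_vars if n in ("temperature", "precipitation", "spei")]
        if not names:
            raise ValueError(f"{path}: no recognised climate variable")
        da = ds[names[0]].load()
    return GriddedClimate(
        latitudes=da["lat"].to_numpy(),
        longitudes=da["lon"].to_numpy(),
        years=da["year"].to_numpy(),
        values=da.to_numpy(),
        variable=str(da.name),
    )
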