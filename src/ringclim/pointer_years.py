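"""Pointer-year detection and climatic attribution.

A pointer year (modified Schweingruber criterion) is a calendar year in
which at least ``threshold`` (default 70%) of at least ``min_trees``
(default 70) trees change ring width in the same direction relative to
the previous year.  First differences are taken on raw ring widths by
default; a tree with a missing ring in either year, or an exact tie,
contributes to the tree count for that year but to neither direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ringclim.core import RingWidthSet
from ringclim.climate_indices import AnomalyClassification

__all__ = ["pointer_years", "attribute_pointer_years"]


def pointer_years(
    rwset: RingWidthSet,
    threshold: float = 0.70,
    min_trees: int = 70,
    use_indices: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify every year as a positive, negative or non-pointer year.

    Parameters
    ----------
    rwset
        The raw ring widths (one series per tree).
    threshold
        Minimum fraction of trees that must agree; must exceed 0.5 so
        positive and negative classes are mutually exclusive.
    min_trees
        Minimum number of trees with a defined first difference.
    use_indices
        Optional year x tree table of detrended indices to difference
        instead of raw widths.

    Returns
    -------
    DataFrame indexed by year with columns ``n`` (trees with a defined
    difference), ``frac_up``, ``frac_down`` and ``cls`` in
    {"positive", "negative", "none"}.  The first year is always "none".
    """
    if not threshold > 0.5:
        raise ValueError("threshold must exceed 0.5")
    tab = use_indices if use_indices is not None else rwset.to_frame()
    if tab.shape[0] < 2:
        raise ValueError("need at least 2 years of data")
    vals = tab.to_numpy(dtype=float)
    present = np.isfinite(vals) & (vals > 0)  # width/index 0 = missing ring
    years = tab.index.to_numpy()

    both = present[1:] & present[:-1]
    diff = vals[1:] - vals[:-1]
    up = both & (diff > 0)
    down = both & (diff < 0)
    n = both.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_up = np.where(n > 0, up.sum(axis=1) / n, np.nan)
        frac_down = np.where(n > 0, down.sum(axis=1) / n, np.nan)

    cls = np.full(len(n), "none", dtype=object)
    eligible = n >= min_trees
    cls[eligible & (frac_up >= threshold)] = "positive"
    cls[eligible & (frac_down >= threshold)] = "negative"

    out = pd.DataFrame(
        {
            "n": np.r_[0, n],
            "frac_up": np.r_[np.nan, frac_up],
            "frac_down": np.r_[np.nan, frac_down],
            "cls": np.r_[["none"], cls],
        },
        index=pd.Index(years, name="year"),
    )
    return out


def attribute_pointer_years(
    py_table: pd.DataFrame,
    temperature_cls: AnomalyClassification,
    precipitation_cls: AnomalyClassification,
    months: range = range(1, 10),
) -> pd.DataFrame:
    """Attach monthly and annual climate percentiles to each pointer year.

    For every detected pointer year the January-September and annual
    percentiles (and annual class labels) for temperature and
    precipitation are joined.  A pointer year outside the climate
    coverage is kept but flagged ``attributed=False``.
    """
    hits = py_table[py_table["cls"] != "none"]
    cols: list[str] = ["cls", "attributed"]
    month_names = [f"{m:02d}" for m in months]
    for var in ("T", "P"):
        cols += [f"{var}_{mn}" for mn in month_names] + [f"{var}_year", f"{var}_year_class"]
    rows = []
    for year, row in hits.iterrows():
        rec: dict[str, object] = {"cls": row["cls"]}
        attributed = (
            year in temperature_cls.percentile.index
            and year in precipitation_cls.percentile.index
        )
        rec["attributed"] = attributed
        for var, cls_tab in (("T", temperature_cls), ("P", precipitation_cls)):
            for m, mn in zip(months, month_names):
                rec[f"{var}_{mn}"] = (
                    cls_tab.percentile.loc[year, m] if attributed else np.nan
                )
            rec[f"{var}_year"] = (
                cls_tab.percentile.loc[year, "annual"] if attributed else np.nan
            )
            rec[f"{var}_year_class"] = (
                cls_tab.label.loc[year, "annual"] if attributed else ""
            )
        rows.append(pd.Series(rec, name=year))
    if not rows:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="year"))
    out = pd.DataFrame(rows)
    out.index.name = "year"
    return out[cols]
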