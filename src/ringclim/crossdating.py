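"""Chronology-agreement statistics: Gleichlaufigkeit and Baillie-Pilcher t.

Both operate on year-indexed series (pandas Series); only the common
year overlap is used and both statistics are symmetric in their
arguments.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["glk", "tbp", "t_from_r", "AgreementStats", "agreement", "agreement_matrix"]


def _overlap(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    common = a.index.intersection(b.index).sort_values()
    av = a.loc[common].to_numpy(dtype=float)
    bv = b.loc[common].to_numpy(dtype=float)
    keep = np.isfinite(av) & np.isfinite(bv)
    return av[keep], bv[keep]


def glk(a: pd.Series, b: pd.Series) -> float:
    """Gleichlaufigkeit (%): sign agreement of year-to-year changes.

    Over the overlap's first differences each year-pair scores 1 when
    both differences share the same nonzero sign, 0.5 when exactly one
    difference is zero, and 0 otherwise (opposite signs, or both zero).
    Returns 100 times the mean score.
    """
    av, bv = _overlap(a, b)
    if len(av) < 2:
        raise ValueError("GLK needs an overlap of at least 2 years")
    sa = np.sign(np.diff(av))
    sb = np.sign(np.diff(bv))
    score = np.where(
        (sa == sb) & (sa != 0),
        1.0,
        np.where((sa == 0) ^ (sb == 0), 0.5, 0.0),
    )
    return float(100.0 * score.mean())


def t_from_r(r: float, n: int) -> float:
    """Student-t transform of a Pearson correlation on n observations."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return math.inf if r > 0 else -math.inf
    return r * math.sqrt((n - 2) / (1.0 - r * r))


def _bp_highpass(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Baillie-Pilcher index: 100 * value / centered moving average, logged.

    The moving-average window shrinks symmetrically at the series ends
    (truncated centered window).
    """
    s = pd.Series(x)
    ma = s.rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    if np.any(ma <= 0) or np.any(x <= 0):
        raise ValueError("Baillie-Pilcher filtering needs strictly positive values")
    return np.log(100.0 * x / ma)


def tbp(a: pd.Series, b: pd.Series, min_overlap: int = 12, window: int = 5) -> float:
    """Baillie-Pilcher t between two series.

    Both series are high-pass filtered (percent of a centered 5-year
    moving average, then natural log); the Pearson correlation of the
    filtered overlap is converted to a t value with ``t_from_r``.  A
    correlation at or beyond +/-1 (e.g. a series against itself) returns
    the sentinel ``math.inf`` (or ``-math.inf``).
    """
    av, bv = _overlap(a, b)
    n = len(av)
    if n < min_overlap:
        raise ValueError(f"overlap {n} below minimum {min_overlap}")
    fa = _bp_highpass(av, window)
    fb = _bp_highpass(bv, window)
    if fa.std() == 0 or fb.std() == 0:
        raise ValueError("zero variance after Baillie-Pilcher filtering")
    r = float(np.corrcoef(fa, fb)[0, 1])
    if r > 1.0 - 1e-12:       # identical series up to float noise
        r = 1.0
    elif r < -1.0 + 1e-12:
        r = -1.0
    return t_from_r(r, n)


class AgreementStats:
    """GLK%, t_BP and overlap length for one pair of chronologies."""

    def __init__(self, glk_percent: float, t_bp: float, overlap_n: int):
        self.glk_percent = glk_percent
        self.t_bp = t_bp
        self.overlap_n = overlap_n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AgreementStats(glk={self.glk_percent:.2f}%, "
            f"t_bp={self.t_bp:.2f}, n={self.overlap_n})"
        )


def agreement(a: pd.Series, b: pd.Series, min_overlap: int = 12) -> AgreementStats:
    """Both agreement statistics for one pair."""
    av, _ = _overlap(a, b)
    return AgreementStats(
        glk_percent=glk(a, b),
        t_bp=tbp(a, b, min_overlap=min_overlap),
        overlap_n=len(av),
    )


def agreement_matrix(chronologies: dict[str, pd.Series], min_overlap: int = 12) -> pd.DataFrame:
    """Pairwise agreement table (rows: pair; columns: glk, t_bp, n)."""
    names = list(chronologies)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            st = agreement(chronologies[na], chronologies[nb], min_overlap=min_overlap)
            rows.append((na, nb, st.glk_percent, st.t_bp, st.overlap_n))
    return pd.DataFrame(rows, columns=["a", "b", "glk_percent", "t_bp", "overlap_n"])
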