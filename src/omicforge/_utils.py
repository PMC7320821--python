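"""Shared numeric helpers: reporting-grade rounding and fast rank correlation."""

from __future__ import annotations

import numpy as np
from scipy import stats


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed summary tables).

    Python's built-in ``round`` is banker's rounding; report tables in this
    field round 0.5 up in magnitude.
    """
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage ``numerator/denominator*100`` rounded half-away-from-zero.

    Raises ``ValueError`` on a zero denominator.
    """
    if denominator == 0:
        raise ValueError("percent() denominator must be non-zero")
    return round_half_away(numerator / denominator * 100.0, decimals)


def rank_rows(values: np.ndarray) -> np.ndarray:
    """Average ranks of each row of a 2-D array (tie-corrected)."""
    values = np.asarray(values, dtype=float)
    return np.apply_along_axis(stats.rankdata, 1, values)


def spearman_rows(values: np.ndarray) -> np.ndarray:
    """Tie-corrected Spearman correlation matrix between the rows of ``values``.

    Implemented as Pearson correlation of average ranks, which is exact for
    tied data.  Rows with zero variance produce NaN rows/columns; callers
    decide how to treat them.
    """
    ranks = rank_rows(values)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.atleast_2d(corr)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0, out=corr)


def spearman_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlations between every row of ``a`` and every row of ``b``.

    Returns an ``(n_a, n_b)`` matrix; pairs involving a constant row are NaN.
    """
    ra = rank_rows(a)
    rb = rank_rows(b)
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra_c**2).sum(axis=1))
    nb = np.sqrt((rb_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (ra_c @ rb_c.T) / np.outer(na, nb)
    corr[na == 0, :] = np.nan
    corr[:, nb == 0] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr)
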