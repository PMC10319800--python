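"""Cohort-level statistics: goodness-of-fit tests and anatomical tuning gradients.

Small wrappers around scipy with the guards and conventions used throughout
the package (chi-square vs uniform for segment counts, exact one-sided
binomial tests for subregion enrichment), plus the 1-mm-segment gradient
analysis that pools tuned-cell counts across animals along a probe axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "chi2_gof",
    "binomial_one_sided",
    "GradientTable",
    "gradient_analysis",
]


def chi2_gof(observed, expected="uniform", *, enforce_min_expected=False):
    """Pearson chi-square goodness-of-fit test.

    Parameters
    ----------
    observed : array-like of int
        Observed counts per category.
    expected : array-like or "uniform"
        Expected counts. ``"uniform"`` spreads the observed total equally.
    enforce_min_expected : bool
        If True, raise when any expected count is below 5 (caller should
        fall back to an exact binomial test in that regime).

    Returns
    -------
    (statistic, df, p) : tuple of float, int, float
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed must be a 1-D array with >= 2 categories")
    if isinstance(expected, str) and expected == "uniform":
        exp = np.full(obs.size, obs.sum() / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.shape != obs.shape:
            raise ValueError("expected counts must match observed shape")
    if np.any(exp <= 0):
        raise ValueError("all expected counts must be > 0")
    if enforce_min_expected and np.any(exp < 5):
        raise ValueError(
            "expected frequencies below 5; use binomial_one_sided instead"
        )
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def binomial_one_sided(k, n, p0=0.5):
    """Exact upper-tail binomial probability P(X >= k | n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p0))


@dataclass
class GradientTable:
    """Tuned-cell counts along a probe axis, pooled across animals.

    Attributes
    ----------
    segments : ndarray
        Segment index (0 = most posterior / most medial, depending on axis).
    counts : DataFrame
        Rows = segments, columns = tuning classes, values = pooled counts of
        tuned cells.
    totals : ndarray
        Total recorded cells per segment (tuned or not).
    proportions : DataFrame
        counts / totals per segment; NaN where a segment holds no cells.
    segment_mm : float
        Physical length of one segment (1 mm by convention).
    """

    segments: np.ndarray
    counts: pd.DataFrame
    totals: np.ndarray
    proportions: pd.DataFrame
    segment_mm: float = 1.0


def gradient_analysis(units, *, n_segments=7, segment_mm=1.0,
                      axis_col="axis_mm", class_col="tuning_class",
                      animal_col="animal"):
    """Pool tuned-cell counts into equal axis segments and test uniformity.

    ``units`` is a DataFrame with one row per recorded cell carrying its
    position along the probe axis in mm (``axis_mm``, already aligned across
    animals), its tuning class (empty/NaN = untuned) and an animal id.
    Counts are summed per 1 mm segment across animals, expressed as a
    proportion of all cells recorded in the segment, and each tuning class is
    tested against a uniform distribution over segments with a chi-square
    goodness-of-fit test.

    Returns (GradientTable, DataFrame of per-class chi2/df/p).
    """
    units = pd.DataFrame(units)
    for col in (axis_col, class_col):
        if col not in units.columns:
            raise ValueError(f"units table is missing column {col!r}")
    if animal_col in units.columns and units[animal_col].nunique() < 2:
        raise ValueError("gradient analysis requires >= 2 animals")

    x = units[axis_col].to_numpy(dtype=float)
    lo = np.nanmin(x)
    extent = n_segments * segment_mm
    seg = np.clip(((x - lo) / segment_mm).astype(int), 0, n_segments - 1)
    out_of_extent = x - lo > extent
    if np.any(out_of_extent):
        seg[out_of_extent] = n_segments - 1  # clamp overhang into last segment

    totals = np.bincount(seg, minlength=n_segments)
    tuned = units[class_col].notna() & (units[class_col].astype(str) != "")
    classes = sorted(units.loc[tuned, class_col].astype(str).unique())
    counts = pd.DataFrame(0, index=np.arange(n_segments), columns=classes)
    for cls in classes:
        m = tuned & (units[class_col].astype(str) == cls)
        counts[cls] = np.bincount(seg[m.to_numpy()], minlength=n_segments)

    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts.div(np.where(totals > 0, totals, np.nan), axis=0)

    rows = []
    for cls in classes:
        obs = counts[cls].to_numpy()
        if obs.sum() == 0:
            continue
        stat, df, p = chi2_gof(obs, "uniform")
        rows.append({"tuning_class": cls, "chi2": stat, "df": df, "p": p})
    tests = pd.DataFrame(rows, columns=["tuning_class", "chi2", "df", "p"])

    table = GradientTable(
        segments=np.arange(n_segments),
        counts=counts,
        totals=totals,
        proportions=props,
        segment_mm=segment_mm,
    )
    return table, tests
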