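"""Cohort-level statistics: descriptive summaries, the exact Wilcoxon
signed-rank test, and reader-rating tallies."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DegenerateDataError, ResourceError, StructuralError

__all__ = [
    "WilcoxonResult",
    "descriptive",
    "wilcoxon_signed_rank_exact",
    "tally_ratings",
    "RATING_CATEGORIES",
]

RATING_CATEGORIES = ("noise", "cortical_structures", "artifacts")

#: Pairs above this size are rejected rather than enumerated (2**n terms).
EXACT_ENUMERATION_CAP = 20


@dataclass(frozen=True)
class WilcoxonResult:
    """Exact signed-rank test result.

    ``w_statistic`` is the smaller of the positive- and negative-rank sums;
    ``n_effective`` counts pairs after dropping zero differences.
    """

    w_statistic: float
    n_effective: int
    p_two_sided: float


def descriptive(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of a cohort column."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise StructuralError("values must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise StructuralError("values must be finite")
    if arr.size < 2:
        raise DegenerateDataError("sample standard deviation needs >= 2 values")
    return float(arr.mean()), float(arr.std(ddof=1))


def wilcoxon_signed_rank_exact(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences receive
    midranks.  The two-sided p-value is computed under the exact null by
    full enumeration of all ``2**n`` sign assignments as
    ``min(1, 2 * min(P(W+ <= w), P(W+ >= w)))`` where ``W+`` is the
    positive-rank sum.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise StructuralError("x and y must be 1-D sequences of equal length")
    if x_arr.size == 0:
        raise StructuralError("need at least one pair")
    d = x_arr - y_arr
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n > EXACT_ENUMERATION_CAP:
        raise ResourceError(
            f"exact enumeration capped at n={EXACT_ENUMERATION_CAP}, got {n}"
        )

    ranks = rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    # doubled ranks are integers even with midranks -> exact integer sums
    r2 = np.round(ranks * 2).astype(np.int64)
    sums = np.zeros(1, dtype=np.int64)
    for r in r2:
        sums = np.concatenate([sums, sums + r])  # all 2**n subset sums of ranks
    w_plus2 = int(round(w_plus * 2))
    total = sums.size
    p_le = np.count_nonzero(sums <= w_plus2) / total
    p_ge = np.count_nonzero(sums >= w_plus2) / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(w_statistic=w, n_effective=int(n), p_two_sided=float(p))


def tally_ratings(table: pd.DataFrame) -> pd.Series:
    """Per-(reader, category) sums of 3-point paired-preference ratings.

    ``table`` is long-form with columns ``case``, ``reader``, ``category``,
    ``rating``; ratings must come from {-1, 0, 1}.
    """
    required = {"case", "reader", "category", "rating"}
    if not isinstance(table, pd.DataFrame) or not required.issubset(table.columns):
        raise StructuralError(f"table must have columns {sorted(required)}")
    if table.empty:
        raise DegenerateDataError("rating table is empty")
    ratings = table["rating"].to_numpy()
    if not np.isin(ratings, (-1, 0, 1)).all():
        raise StructuralError("ratings must come from the 3-point scale {-1, 0, 1}")
    unknown = set(table["category"]) - set(RATING_CATEGORIES)
    if unknown:
        raise StructuralError(f"unknown rating categories: {sorted(unknown)}")
    return table.groupby(["reader", "category"], sort=True)["rating"].sum()
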