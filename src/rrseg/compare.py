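"""Group comparisons: Mann-Whitney U tests and correlations.

Cohort-level questions ("are CHF gamma values shifted relative to healthy
subjects?") are answered with the Mann-Whitney U test on per-subject
summary statistics; continuous associations (sdNN against %mu50) use the
product-moment correlation, with a rank alternative exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import EmptyInputError, UndefinedStatisticError

__all__ = ["GroupComparison", "mann_whitney_u", "pearson_r", "spearman_r"]

#: Combined sample size at or below which the exact null distribution of U
#: is enumerated rather than approximated.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of one measure between two groups."""

    measure_name: str
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str  # "exact" | "asymptotic"


def _u_from_ranks(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def _exact_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all group-A label assignments."""
    n = pooled_ranks.size
    n_b = n - n_a
    total = comb(n, n_a)
    offset = n_a * (n_a + 1) / 2.0
    us = np.fromiter(
        (sum(pooled_ranks[i] for i in idx) - offset
         for idx in combinations(range(n), n_a)),
        dtype=np.float64, count=total)
    mid = n_a * n_b / 2.0
    lo = np.sum(us <= u_obs) / total
    hi = np.sum(us >= u_obs) / total
    if u_obs == mid:
        return 1.0
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   measure_name: str = "measure", group_a: str = "A",
                   group_b: str = "B", method: str = "auto",
                   ) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    ``method`` is ``"exact"`` (full enumeration over label assignments,
    valid with ties), ``"asymptotic"`` (normal approximation with tie and
    continuity corrections) or ``"auto"``: exact when the pooled sample
    has at most 12 observations, asymptotic otherwise.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise EmptyInputError("both groups need at least two observations")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u = _u_from_ranks(ranks[:n_a], n_a, n_b)

    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "asymptotic"
    if method == "exact":
        p = _exact_p(ranks, n_a, u)
    elif method == "asymptotic":
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            mid = n_a * n_b / 2.0
            z = (abs(u - mid) - 0.5) / np.sqrt(var_u)
            p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(measure_name=measure_name, group_a=group_a,
                           group_b=group_b, u_statistic=u, p_value=p,
                           n_a=n_a, n_b=n_b, method=method)


def _check_paired(x, y):
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size or x.size < 3:
        raise EmptyInputError("need paired samples of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined for a zero-variance sample")
    return x, y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two paired samples."""
    x, y = _check_paired(x, y)
    return float(sps.pearsonr(x, y).statistic)


def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation alternative to :func:`pearson_r`."""
    x, y = _check_paired(x, y)
    return float(sps.spearmanr(x, y).statistic)
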