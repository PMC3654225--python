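"""Low-level scan kernel for the maximal weighted KS statistic.

The scan visits every cut position p (left part = x[:p+1]) and needs, for
each, the sup-norm distance between the left and right empirical CDFs.
Writing c_p(k) for the number of left elements with value rank <= k and
C(k) for the same count over the whole sequence, the unnormalised ECDF
difference at rank k is

    n * c_p(k) - (p + 1) * C(k)            (an integer),

so D_KS(p) = max_k |n c_p(k) - n_L C(k)| / (n_L n_R) and the weighted
statistic D(p) = D_KS(p) * sqrt(n_L n_R / n).  Advancing the pointer by one
beat updates the integer profile in O(n), giving an O(n^2) scan with a tiny
constant; numba compiles the inner loop when available.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


def rank_encode(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense ranks of ``x`` over its sorted unique values, plus cumulative
    counts ``C`` with ``C[k] = #{x_i <= k-th unique value}``."""
    _, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    C = np.cumsum(counts)
    return inv.astype(np.int64), C.astype(np.int64)


@njit(cache=False)
def _scan_best(ranks, C, n, min_side):  # pragma: no cover - numba path
    m = C.shape[0]
    g = np.zeros(m, np.int64)
    best_score = -1.0
    best_p = -1
    best_num = 0
    for p in range(n - 1):
        r = ranks[p]
        maxabs = 0
        for k in range(r):
            v = g[k] - C[k]
            g[k] = v
            if v < 0:
                v = -v
            if v > maxabs:
                maxabs = v
        for k in range(r, m):
            v = g[k] - C[k] + n
            g[k] = v
            if v < 0:
                v = -v
            if v > maxabs:
                maxabs = v
        nl = p + 1
        nr = n - nl
        if nl >= min_side and nr >= min_side:
            score = maxabs / math.sqrt(nl * nr)
            if score > best_score:
                best_score = score
                best_p = p
                best_num = maxabs
    return best_p, best_num


def _scan_best_numpy(ranks, C, n, min_side):
    # vectorised fallback mirroring _scan_best
    m = C.shape[0]
    g = np.zeros(m, np.int64)
    best_score = -1.0
    best_p = -1
    best_num = 0
    for p in range(n - 1):
        r = ranks[p]
        g -= C
        g[r:] += n
        nl = p + 1
        nr = n - nl
        if nl >= min_side and nr >= min_side:
            maxabs = int(np.abs(g).max())
            score = maxabs / math.sqrt(nl * nr)
            if score > best_score:
                best_score = score
                best_p = p
                best_num = maxabs
    return best_p, best_num


def scan_best(x: np.ndarray, min_side: int) -> tuple[int, float, float]:
    """Return ``(index, d_ks, d)`` of the admissible cut maximising the
    weighted KS statistic; ties broken toward the smallest index."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.shape[0]
    ranks, C = rank_encode(x)
    if HAVE_NUMBA:
        best_p, best_num = _scan_best(ranks, C, n, min_side)
    else:
        best_p, best_num = _scan_best_numpy(ranks, C, n, min_side)
    if best_p < 0:
        raise ValueError("no admissible cut position")
    nl = best_p + 1
    nr = n - nl
    d_ks = best_num / (nl * nr)
    d = d_ks * math.sqrt(nl * nr / n)
    return best_p, d_ks, d
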