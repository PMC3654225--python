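"""Distribution summaries of the segment population and their fits.

Three parametric summaries characterise how a record fragments:

* the tail of the segment-length distribution, modelled on the
  complementary cumulative distribution as a two-exponential mixture
  ``A exp(-(L - l0)/L1) + (1 - A) exp(-(L - l0)/L2)`` with a short scale
  L1 and a long scale L2;
* the distribution of per-segment variances, whose log-log probability
  density is fitted by a parabola
  ``log10 PDF(s2) = c2 [log10 s2]^2 + c1 log10 s2 + c0``
  (for log-normally distributed variances the parabola is exact);
* the scaling of the mean within-segment variance with segment length,
  ``<s2(L)> ~ L^xi`` -- xi near 0 indicates white-noise-like patches,
  xi near 1 Brownian-like ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import Segment
from .exceptions import (
    CurveFitError,
    DegenerateInputError,
    EmptyInputError,
    InsufficientDataError,
)

__all__ = [
    "ECCDF",
    "windowed_segments",
    "eccdf",
    "LengthTailFit",
    "fit_length_tail",
    "VarPdfFit",
    "fit_var_pdf",
    "mean_variance_by_length",
    "ScalingFit",
    "fit_scaling_exponent",
]


class ECCDF:
    """Empirical complementary CDF with the >= convention.

    ``ECCDF(values)(v)`` returns ``#{x >= v} / n``; at the sample minimum
    the value is exactly 1 and the function is non-increasing.
    """

    def __init__(self, values: Sequence[float]):
        vals = np.asarray(values, dtype=np.float64).ravel()
        if vals.size == 0:
            raise EmptyInputError("ECCDF of an empty sample is undefined")
        self._sorted = np.sort(vals)
        self.n = vals.size
        self.support = np.unique(self._sorted)
        self.probs = self(self.support)

    def __call__(self, v):
        v = np.asarray(v, dtype=np.float64)
        ge = self.n - np.searchsorted(self._sorted, v, side="left")
        out = ge / self.n
        return float(out) if out.ndim == 0 else out


def eccdf(values: Sequence[float]) -> ECCDF:
    """Complementary empirical CDF of ``values`` (see :class:`ECCDF`)."""
    return ECCDF(values)


@dataclass(frozen=True)
class LengthTailFit:
    """Two-exponential mixture fit of the segment-length CCDF.

    ``A`` is the weight of the short scale ``L1``; ``L2 >= L1`` is the
    long scale governing the far tail; ``l0`` is the left edge (the
    minimum segment length), where the model CCDF equals 1.
    """

    A: float
    L1: float
    L2: float
    l0: float
    rss: Optional[float] = None

    def ccdf(self, L):
        L = np.asarray(L, dtype=np.float64)
        return (self.A * np.exp(-(L - self.l0) / self.L1)
                + (1.0 - self.A) * np.exp(-(L - self.l0) / self.L2))


def _tail_model(L, A, L1, L2, l0):
    return A * np.exp(-(L - l0) / L1) + (1.0 - A) * np.exp(-(L - l0) / L2)


def _tail_init(lengths: np.ndarray, l0: float) -> tuple[float, float, float]:
    # two-piece log-linear split of the empirical CCDF at the median
    emp = ECCDF(lengths)
    grid = emp.support.astype(float)
    cc = emp.probs
    med = float(np.median(lengths))
    lo = (grid <= med) & (cc > 0)
    hi = (grid > med) & (cc > 0)
    L1 = L2 = max(med - l0, 1.0)
    A = 0.7
    if lo.sum() >= 2:
        s = np.polyfit(grid[lo] - l0, np.log(cc[lo]), 1)[0]
        if s < 0:
            L1 = -1.0 / s
    if hi.sum() >= 2:
        s, icpt = np.polyfit(grid[hi] - l0, np.log(cc[hi]), 1)
        if s < 0:
            L2 = -1.0 / s
            A = float(np.clip(1.0 - np.exp(icpt), 0.05, 0.95))
    if L1 > L2:
        L1, L2, A = L2, L1, 1.0 - A
    return A, L1, L2


def fit_length_tail(lengths: Sequence[float], l0: float) -> LengthTailFit:
    """Fit the two-exponential CCDF model to observed segment lengths.

    Nonlinear least squares against the empirical CCDF evaluated at the
    observed (unique) lengths; A is constrained to [0, 1] and the scales
    are positive, with L1 <= L2 restored by relabelling after the fit.
    """
    lengths = np.asarray(lengths, dtype=np.float64).ravel()
    if lengths.size < 50:
        raise InsufficientDataError(
            f"need at least 50 segment lengths, got {lengths.size}")
    if np.any(lengths < l0):
        raise ValueError("all lengths must be >= l0")
    if np.unique(lengths).size < 3:
        raise DegenerateInputError("length sample is (nearly) constant")
    emp = ECCDF(lengths)
    grid = emp.support.astype(float)
    target = emp.probs
    A0, L10, L20 = _tail_init(lengths, l0)
    span = float(lengths.max() - l0) or 1.0
    try:
        popt, _ = curve_fit(
            lambda L, A, L1, L2: _tail_model(L, A, L1, L2, l0),
            grid, target,
            p0=(A0, min(L10, 100 * span), min(L20, 100 * span)),
            bounds=([0.0, 1e-6, 1e-6], [1.0, 1e3 * span, 1e3 * span]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise CurveFitError(f"length-tail fit did not converge: {exc}")
    A, L1, L2 = (float(v) for v in popt)
    if L1 > L2:
        L1, L2, A = L2, L1, 1.0 - A
    rss = float(np.sum((target - _tail_model(grid, A, L1, L2, l0)) ** 2))
    return LengthTailFit(A=A, L1=L1, L2=L2, l0=float(l0), rss=rss)


@dataclass(frozen=True)
class VarPdfFit:
    """Quadratic fit of log10 PDF(sigma^2) against log10 sigma^2.

    ``c2, c1, c0`` are the quadratic, linear and constant coefficients
    (the latter is the gamma parameter used to discriminate cohorts).
    """

    c2: float
    c1: float
    c0: float
    bin_edges: np.ndarray
    rss: Optional[float] = None

    @property
    def gamma(self) -> float:
        return self.c0

    def log10_pdf(self, sigma2):
        y = np.log10(np.asarray(sigma2, dtype=np.float64))
        return self.c2 * y**2 + self.c1 * y + self.c0


def fit_var_pdf(variances: Sequence[float], n_bins: int = 25) -> VarPdfFit:
    """Histogram-based quadratic fit of the log variance density.

    The histogram is taken on log10 sigma^2 with ``n_bins`` equal-width
    bins; the density is expressed per unit of sigma^2 (so the PDF
    integrates to 1 over sigma^2) and ordinary least squares is run on
    the non-empty bins only.
    """
    v = np.asarray(variances, dtype=np.float64).ravel()
    if v.size < 50:
        raise InsufficientDataError(
            f"need at least 50 variances, got {v.size}")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    y = np.log10(v)
    if np.ptp(y) == 0:
        raise DegenerateInputError("all variances identical; histogram empty")
    counts, edges = np.histogram(y, bins=n_bins)
    width = edges[1] - edges[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 5:
        raise InsufficientDataError(
            f"only {int(keep.sum())} non-empty bins (need >= 5)")
    # density of y, then change of variable to sigma^2: p(s2) = p_y / (s2 ln 10)
    dens_y = counts[keep] / (v.size * width)
    log_pdf = np.log10(dens_y) - centers[keep] - np.log10(np.log(10.0))
    c2, c1, c0 = np.polyfit(centers[keep], log_pdf, 2)
    rss = float(np.sum(
        (log_pdf - np.polyval([c2, c1, c0], centers[keep])) ** 2))
    return VarPdfFit(c2=float(c2), c1=float(c1), c0=float(c0),
                     bin_edges=edges, rss=rss)


def mean_variance_by_length(segments: Sequence[Segment],
                            n_bins: int = 10) -> pd.DataFrame:
    """Mean within-segment variance per logarithmic length bin.

    Returns a DataFrame with one row per non-empty bin: geometric-mean
    length ``L``, ``mean_var`` and ``count``.
    """
    segments = list(segments)
    if len(segments) < 20:
        raise InsufficientDataError(
            f"need at least 20 segments, got {len(segments)}")
    lengths = np.array([s.length for s in segments], dtype=np.float64)
    variances = np.array([s.var for s in segments], dtype=np.float64)
    lmin, lmax = lengths.min(), lengths.max()
    if lmin == lmax:
        return pd.DataFrame({"L": [lmin], "mean_var": [variances.mean()],
                             "count": [len(segments)]})
    edges = np.geomspace(lmin, lmax, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, lengths, side="right") - 1,
                  0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = idx == k
        if not sel.any():
            continue
        rows.append({
            "L": float(np.exp(np.mean(np.log(lengths[sel])))),
            "mean_var": float(variances[sel].mean()),
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def windowed_segments(x, lengths_cycle: Sequence[int]) -> List[Segment]:
    """Tile ``x`` with consecutive windows of the given lengths (cycled).

    Returns :class:`Segment` objects carrying each window's sample mean
    and population variance.  This provides variance-scaling references
    on processes without planted patches (pure noise, random walks):
    unlike segmentation-derived patches, fixed windows are not selected
    for internal stationarity, so a process with window variance
    proportional to L^xi yields the exponent xi without selection bias.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    cycle = [int(L) for L in lengths_cycle]
    if not cycle or min(cycle) < 2:
        raise ValueError("window lengths must all be >= 2")
    segs: List[Segment] = []
    pos = 0
    i = 0
    while pos + cycle[i % len(cycle)] <= x.size:
        L = cycle[i % len(cycle)]
        chunk = x[pos:pos + L]
        segs.append(Segment(pos, pos + L, float(chunk.mean()),
                            float(chunk.var())))
        pos += L
        i += 1
    return segs


@dataclass(frozen=True)
class ScalingFit:
    """Power-law fit <sigma^2(L)> ~ L^xi of binned mean variances."""

    xi: float
    intercept: float
    fit_range: tuple
    bin_stats: pd.DataFrame
    rss: Optional[float] = None


def fit_scaling_exponent(bin_stats: pd.DataFrame,
                         fit_range: Optional[tuple] = None,
                         min_count: int = 5) -> ScalingFit:
    """Least-squares slope of log10 mean variance against log10 length.

    Only bins holding at least ``min_count`` segments (and lying inside
    ``fit_range``, when given) enter the fit; at least four such bins are
    required.
    """
    stats = bin_stats[bin_stats["count"] >= min_count]
    if fit_range is not None:
        lo, hi = fit_range
        stats = stats[(stats["L"] >= lo) & (stats["L"] <= hi)]
    if len(stats) < 4:
        raise InsufficientDataError(
            f"only {len(stats)} usable bins (need >= 4)")
    lx = np.log10(stats["L"].to_numpy())
    ly = np.log10(stats["mean_var"].to_numpy())
    xi, icpt = np.polyfit(lx, ly, 1)
    rss = float(np.sum((ly - (xi * lx + icpt)) ** 2))
    rng = fit_range if fit_range is not None else (
        float(stats["L"].min()), float(stats["L"].max()))
    return ScalingFit(xi=float(xi), intercept=float(icpt), fit_range=rng,
                      bin_stats=bin_stats, rss=rss)
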