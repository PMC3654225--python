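"""Recursive Kolmogorov-Smirnov segmentation of a time series.

The algorithm splits a series into patches that are internally stationary
in distribution.  For every candidate cut the two-sample KS distance
between the left and right empirical CDFs is weighted by the effective
sample size,

    D = D_KS * (1/n_L + 1/n_R)^(-1/2),

and the cut with maximal D is tested against a critical value

    D_crit(n) = a * (ln n - b)^c,

the Monte-Carlo 1 - alpha quantile of max-D over i.i.d. sequences of the
same length (see :mod:`rrseg.calibration`).  A significant cut whose two
parts both reach the minimum length ``l_min`` is accepted and the
procedure recurses, left patch first, until no patch can be split.

Because the KS statistic is distribution-free for continuous i.i.d. data,
the same critical curve applies whatever the marginal distribution of the
noise is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._kernels import scan_best
from .exceptions import RRSegError

__all__ = [
    "SegmentationParams",
    "CriticalCurve",
    "CutCandidate",
    "CutDecision",
    "Segment",
    "SegmentationResult",
    "DEFAULT_CURVE",
    "ks_distance",
    "scan_cut",
    "critical_value",
    "segment",
    "KSSegmenter",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning knobs of the recursive segmentation.

    p0 : confidence level of the significance gate (alpha = 1 - p0).
    l_min : minimum accepted segment length, beats.  The default 30 is
        half a period of the 0.03 Hz upper VLF edge at 1 beat/s.
    min_side : smallest sample size per side considered during the scan.
    """

    p0: float = 0.95
    l_min: int = 30
    min_side: int = 2

    def __post_init__(self):
        if not (0.0 < self.p0 < 1.0):
            raise ValueError("p0 must lie strictly between 0 and 1")
        if self.l_min < 2:
            raise ValueError("l_min must be >= 2")
        if self.min_side < 2:
            raise ValueError("min_side must be >= 2")


@dataclass(frozen=True)
class CriticalCurve:
    """Critical value of the maximal weighted KS statistic, a(ln n - b)^c.

    ``p0`` records the confidence level the curve was calibrated at;
    ``rss`` optionally carries the residual sum of squares of the fit.
    The curve is defined only for n > e**b.
    """

    a: float
    b: float
    c: float
    p0: float = 0.95
    rss: Optional[float] = None

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError("curve requires a > 0 and c > 0")
        if not (0.0 < self.p0 < 1.0):
            raise ValueError("p0 must lie strictly between 0 and 1")

    def __call__(self, n: int) -> float:
        return critical_value(n, self)


#: Published reference curve for p0 = 0.95; `rrseg calibrate` regenerates it.
DEFAULT_CURVE = CriticalCurve(a=1.52, b=1.80, c=0.14, p0=0.95)


@dataclass(frozen=True)
class CutCandidate:
    """A candidate cut: ``index`` is the last 0-based index of the left part."""

    index: int
    d_ks: float
    d: float
    n_left: int
    n_right: int


@dataclass(frozen=True)
class CutDecision:
    """One accept/reject decision taken during the recursion.

    ``offset`` locates the examined patch in the full series, so the
    global cut position is ``offset + candidate.index``.
    """

    offset: int
    n_sub: int
    candidate: Optional[CutCandidate]
    threshold: Optional[float]
    accepted: bool
    reason: str  # "accepted" | "not_significant" | "min_length" | "too_short"


@dataclass(frozen=True)
class Segment:
    """A stationary patch ``[start, end)`` with its first two moments.

    ``mu`` is the mean of the covered values (ms for RR data) and ``var``
    the population variance (divided by L, not L-1), which makes the
    trend/residual variance decomposition of :mod:`rrseg.metrics` exact.
    """

    start: int
    end: int
    mu: float
    var: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment span must be non-empty")
        if self.var < 0:
            raise ValueError("variance cannot be negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    #: alias matching the usual symbol L
    L = length


@dataclass
class SegmentationResult:
    """Segments covering ``[0, n)`` plus the full decision log."""

    segments: List[Segment]
    params: SegmentationParams
    curve: CriticalCurve
    cut_log: List[CutDecision] = field(default_factory=list)
    n: int = 0
    record_id: str = "record"

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments], dtype=int)

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mu for s in self.segments], dtype=float)

    @property
    def variances(self) -> np.ndarray:
        return np.array([s.var for s in self.segments], dtype=float)

    @property
    def change_points(self) -> np.ndarray:
        """Interior boundaries (start indices of all but the first segment)."""
        return np.array([s.start for s in self.segments[1:]], dtype=int)

    def to_frame(self) -> "pd.DataFrame":  # noqa: F821 - forward ref
        import pandas as pd

        return pd.DataFrame(
            {
                "record_id": self.record_id,
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "L": [s.length for s in self.segments],
                "mu_ms": [s.mu for s in self.segments],
                "var_ms2": [s.var for s in self.segments],
            }
        )


def ks_distance(left: Sequence[float], right: Sequence[float]) -> CutCandidate:
    """Weighted two-sample KS statistic between two samples.

    ``d_ks`` is the sup-distance between the two empirical CDFs evaluated
    on the union of observed values (so ties are handled exactly), and
    ``d = d_ks * (1/n_L + 1/n_R)^(-1/2)``.
    """
    left = np.asarray(left, dtype=np.float64).ravel()
    right = np.asarray(right, dtype=np.float64).ravel()
    nl, nr = left.size, right.size
    if nl < 1 or nr < 1:
        raise RRSegError("both samples must contain at least one element")
    grid = np.union1d(left, right)
    fl = np.searchsorted(np.sort(left), grid, side="right") / nl
    fr = np.searchsorted(np.sort(right), grid, side="right") / nr
    d_ks = float(np.max(np.abs(fl - fr)))
    d = d_ks * math.sqrt(nl * nr / (nl + nr))
    return CutCandidate(index=nl - 1, d_ks=d_ks, d=d, n_left=nl, n_right=nr)


def scan_cut(x: Sequence[float], min_side: int = 2) -> CutCandidate:
    """Cut position maximising the weighted KS statistic D.

    Scans every position with at least ``min_side`` points on each side;
    ties are broken toward the smallest index.  O(n^2) worst case with a
    small constant (incremental integer update of the ECDF difference).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.size
    if min_side < 1:
        raise ValueError("min_side must be >= 1")
    if n < 2 * min_side:
        raise RRSegError(
            f"sequence of length {n} too short for min_side={min_side}")
    idx, d_ks, d = scan_best(x, min_side)
    return CutCandidate(index=int(idx), d_ks=float(d_ks), d=float(d),
                        n_left=int(idx) + 1, n_right=int(n - idx - 1))


def critical_value(n: int, curve: CriticalCurve = DEFAULT_CURVE) -> float:
    """Evaluate the critical curve a(ln n - b)^c at sequence length ``n``."""
    ln = math.log(n)
    if ln <= curve.b:
        raise RRSegError(
            f"critical curve undefined for n={n} (requires ln n > b={curve.b})")
    return curve.a * (ln - curve.b) ** curve.c


def _make_segment(x: np.ndarray, start: int, end: int) -> Segment:
    chunk = x[start:end]
    return Segment(start=start, end=end, mu=float(chunk.mean()),
                   var=float(chunk.var()))


def segment(x: Sequence[float], params: Optional[SegmentationParams] = None,
            curve: CriticalCurve = DEFAULT_CURVE,
            record_id: str = "record") -> SegmentationResult:
    """Recursively segment ``x`` into stationary patches.

    A patch is split at the maximal-D cut iff (i) D exceeds the critical
    value for the patch length and (ii) both parts are at least ``l_min``
    long; patches shorter than ``2 * l_min`` are terminal without a scan.
    The recursion is depth-first, left patch first.
    """
    params = params or SegmentationParams()
    if curve.p0 != params.p0:
        raise ValueError(
            f"curve calibrated at p0={curve.p0} but params request p0={params.p0}")
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.size
    if n < 1:
        raise RRSegError("cannot segment an empty series")

    segments: List[Segment] = []
    log: List[CutDecision] = []
    stack = [(0, n)]
    while stack:
        start, end = stack.pop()
        n_sub = end - start
        if n_sub < 2 * params.l_min or n_sub < 2 * params.min_side:
            log.append(CutDecision(start, n_sub, None, None, False, "too_short"))
            segments.append(_make_segment(x, start, end))
            continue
        cand = scan_cut(x[start:end], params.min_side)
        threshold = critical_value(n_sub, curve)
        left_len = cand.index + 1
        right_len = n_sub - left_len
        if cand.d <= threshold:
            log.append(CutDecision(start, n_sub, cand, threshold, False,
                                   "not_significant"))
            segments.append(_make_segment(x, start, end))
        elif left_len < params.l_min or right_len < params.l_min:
            log.append(CutDecision(start, n_sub, cand, threshold, False,
                                   "min_length"))
            segments.append(_make_segment(x, start, end))
        else:
            log.append(CutDecision(start, n_sub, cand, threshold, True,
                                   "accepted"))
            cut = start + cand.index + 1  # first index of the right part
            stack.append((cut, end))
            stack.append((start, cut))
    return SegmentationResult(segments=segments, params=params, curve=curve,
                              cut_log=log, n=n, record_id=record_id)


class KSSegmenter(BaseEstimator):
    """Scikit-learn style estimator wrapping :func:`segment`.

    ``fit`` takes a 1-d series (or single-column array) and exposes the
    fitted patches; ``predict`` labels every sample with its segment index
    and ``transform`` returns the series with each segment's mean removed
    (the detrended series RR*).

    Parameters
    ----------
    p0 : float
        Confidence level of the cut test.
    l_min : int
        Minimum segment length in samples.
    min_side : int
        Minimum per-side sample size during the scan.
    curve : CriticalCurve or None
        Critical curve calibrated at ``p0``; defaults to the published
        coefficients for p0 = 0.95.

    Attributes
    ----------
    result_ : SegmentationResult
    segments_ : list of Segment
    change_points_ : ndarray of interior boundaries
    labels_ : ndarray, segment index of every sample
    n_segments_ : int
    """

    def __init__(self, p0: float = 0.95, l_min: int = 30, min_side: int = 2,
                 curve: Optional[CriticalCurve] = None):
        self.p0 = p0
        self.l_min = l_min
        self.min_side = min_side
        self.curve = curve

    def _validate_series(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=np.float64)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("KSSegmenter expects a 1-d series "
                             f"(got shape {np.asarray(X).shape})")
        if x.size < 1 or not np.all(np.isfinite(x)):
            raise ValueError("series must be non-empty and finite")
        return x

    def fit(self, X, y=None):
        x = self._validate_series(X)
        curve = self.curve if self.curve is not None else DEFAULT_CURVE
        params = SegmentationParams(p0=self.p0, l_min=self.l_min,
                                    min_side=self.min_side)
        self.result_ = segment(x, params, curve)
        self.segments_ = self.result_.segments
        self.change_points_ = self.result_.change_points
        self.n_segments_ = self.result_.n_segments
        labels = np.empty(x.size, dtype=int)
        for i, s in enumerate(self.segments_):
            labels[s.start:s.end] = i
        self.labels_ = labels
        self.n_features_in_ = 1
        return self

    def predict(self, X=None):
        """Segment label of every sample of the fitted series."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "labels_")
        return self.labels_

    def transform(self, X):
        """Remove the fitted per-segment means from ``X`` (detrending)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        x = self._validate_series(X)
        if x.size != self.result_.n:
            raise ValueError("transform input must match the fitted length")
        trend = np.empty_like(x)
        for s in self.segments_:
            trend[s.start:s.end] = s.mu
        return x - trend

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
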