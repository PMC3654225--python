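"""Per-record non-stationarity statistics built on the segmentation.

The segment means define a piecewise-constant trend; subtracting it gives
the detrended series RR*.  Because each segment's residual sums to zero,
the population variance splits exactly:

    var(x) = var(trend) + var(residual)  =  sigma2_T + sigma2_star.

%mu50 is the segment-level analogue of pNN50: the percentage of jumps
between consecutive segment means exceeding 50 ms.  L>300 counts segments
longer than 300 beats (about five minutes of normal rhythm).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np

from .core import SegmentationResult
from .exceptions import RRSegError, UndefinedStatisticError

__all__ = [
    "SubjectSummary",
    "jump_sizes",
    "percent_mu50",
    "count_long_segments",
    "detrend_by_segment_means",
    "summarize_record",
    "JUMP_THRESHOLD_MS",
    "LONG_SEGMENT_BEATS",
]

#: Jump-size threshold of %mu50, ms (the pNN50 convention).
JUMP_THRESHOLD_MS = 50.0

#: Length above which a segment counts as "long" (strictly greater).
LONG_SEGMENT_BEATS = 300


@dataclass(frozen=True)
class SubjectSummary:
    """Flat per-record summary of the segmentation statistics."""

    record_id: str
    group_label: Optional[str]
    n_beats: int
    n_segments: int
    pct_mu50: Optional[float]  # undefined with a single segment
    n_long: int
    var_total: float  # population variance of the series, ms^2
    var_trend: float  # sigma2_T, ms^2
    var_detrended: float  # sigma2_star, ms^2
    jumps: tuple

    def to_dict(self) -> dict:
        d = asdict(self)
        d["jumps"] = list(self.jumps)
        return d


def jump_sizes(result: SegmentationResult) -> np.ndarray:
    """Absolute differences |mu_{i+1} - mu_i| of consecutive segment means."""
    if result.n_segments < 1:
        raise RRSegError("result contains no segments")
    return np.abs(np.diff(result.means))


def percent_mu50(result: SegmentationResult,
                 threshold_ms: float = JUMP_THRESHOLD_MS) -> float:
    """Percentage of consecutive-segment mean jumps exceeding 50 ms."""
    if result.n_segments < 2:
        raise UndefinedStatisticError(
            "%mu50 needs at least two segments (no jumps exist)")
    jumps = jump_sizes(result)
    return 100.0 * float(np.mean(jumps > threshold_ms))


def count_long_segments(result: SegmentationResult,
                        long_threshold: int = LONG_SEGMENT_BEATS) -> int:
    """Number of segments with L strictly greater than ``long_threshold``."""
    return int(np.sum(result.lengths > long_threshold))


def detrend_by_segment_means(x, result: SegmentationResult
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Split ``x`` into (trend, residual) using the fitted segment means.

    The trend repeats each segment's mean across its span; the residual is
    ``x - trend`` and has zero mean within every segment (up to rounding).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if result.n != x.size:
        raise RRSegError(
            f"segmentation covers {result.n} samples, series has {x.size}")
    trend = np.empty_like(x)
    covered = 0
    for s in result.segments:
        trend[s.start:s.end] = s.mu
        covered += s.length
    if covered != x.size:
        raise RRSegError("segments do not cover the series")
    return trend, x - trend


def summarize_record(x, result: SegmentationResult,
                     record_id: Optional[str] = None,
                     group_label: Optional[str] = None,
                     long_threshold: int = LONG_SEGMENT_BEATS) -> SubjectSummary:
    """Assemble the per-record summary used by the cohort comparisons."""
    x = np.asarray(x, dtype=np.float64).ravel()
    trend, resid = detrend_by_segment_means(x, result)
    jumps = jump_sizes(result)
    pct = (percent_mu50(result) if result.n_segments >= 2 else None)
    return SubjectSummary(
        record_id=record_id or result.record_id,
        group_label=group_label,
        n_beats=x.size,
        n_segments=result.n_segments,
        pct_mu50=pct,
        n_long=count_long_segments(result, long_threshold),
        var_total=float(x.var()),
        var_trend=float(trend.var()),
        var_detrended=float(resid.var()),
        jumps=tuple(float(j) for j in jumps),
    )
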