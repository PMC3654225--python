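"""RR-interval series: reading, writing and artifact filtering.

An RR series is the sequence of times between consecutive heart beats,
stored in milliseconds.  Files are plain text with one interval per line;
lines starting with ``#`` are comments.  Ectopic beats and measurement
artifacts are replaced by a running-median estimate before segmentation,
because a single spurious 2000 ms interval is enough to distort the
empirical distribution a segment is judged by.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    EmptyInputError,
    RRParseError,
)

__all__ = [
    "RRSeries",
    "read_rr_text",
    "write_rr_text",
    "filter_ectopic",
    "write_segment_table",
    "read_segment_table",
]

#: Default adaptive-filter tolerance: a beat deviating from the local
#: running median by more than this fraction is treated as ectopic.
DEFAULT_REL_TOL = 0.2

#: Default physiological bounds for a credible RR interval, in ms.
DEFAULT_ABS_BOUNDS = (300.0, 2000.0)

#: Number of accepted beats the running median looks back over.
FILTER_WINDOW = 11


@dataclass(frozen=True)
class RRSeries:
    """An ordered series of beat-to-beat (RR) intervals in milliseconds.

    Parameters
    ----------
    intervals : ndarray
        Strictly positive intervals, ms.
    record_id : str
        Label identifying the recording.
    group_label : str, optional
        Cohort label such as ``"CHF"``, ``"EH"`` or ``"YH"``.
    n_filtered : int
        Number of beats replaced by the artifact filter.
    """

    intervals: np.ndarray
    record_id: str = "record"
    group_label: Optional[str] = None
    n_filtered: int = 0

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=np.float64).ravel()
        if arr.size < 1:
            raise EmptyInputError("an RR series must contain at least one interval")
        if not np.all(arr > 0):
            raise ValueError("RR intervals must be strictly positive")
        if not (0 <= self.n_filtered <= arr.size):
            raise ValueError("n_filtered must lie in [0, len(series)]")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_s(self) -> float:
        """Total record duration in seconds (sum of intervals)."""
        return float(self.intervals.sum() / 1000.0)


def read_rr_text(path, unit_hint: str = "ms", record_id: Optional[str] = None,
                 group_label: Optional[str] = None) -> RRSeries:
    """Read a one-interval-per-line text file into an :class:`RRSeries`.

    ``unit_hint`` is one of ``"ms"``, ``"s"`` or ``"auto"``.  With ``auto``,
    a median below 10 marks the file as seconds (no heart beats 10 ms or
    6000 ms apart for half a record) and values are converted to ms.
    A ``# record_id: <name>`` comment, as written by :func:`write_rr_text`,
    overrides the file-stem record id.
    """
    if unit_hint not in ("ms", "s", "auto"):
        raise ValueError(f"unit_hint must be 'ms', 's' or 'auto', got {unit_hint!r}")
    path = Path(path)
    values = []
    header_id = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("# record_id:"):
                header_id = line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError:
                raise RRParseError(path, lineno, line) from None
            if not np.isfinite(v) or v <= 0:
                raise RRParseError(path, lineno, line)
            values.append(v)
    if not values:
        raise EmptyInputError(f"{path}: no RR intervals found")
    arr = np.asarray(values, dtype=np.float64)
    unit = unit_hint
    if unit == "auto":
        unit = "s" if float(np.median(arr)) < 10.0 else "ms"
    if unit == "s":
        arr = arr * 1000.0
    return RRSeries(arr, record_id=record_id or header_id or path.stem,
                    group_label=group_label)


def write_rr_text(series: RRSeries, path) -> None:
    """Write an RR series as one ms value per line (repr round-trips)."""
    with open(path, "w") as fh:
        fh.write(f"# record_id: {series.record_id}\n")
        for v in series.intervals:
            fh.write(f"{float(v)!r}\n")


def filter_ectopic(series: RRSeries, rel_tol: float = DEFAULT_REL_TOL,
                   abs_bounds: tuple[float, float] = DEFAULT_ABS_BOUNDS) -> RRSeries:
    """Replace ectopic/artifact beats by a running-median estimate.

    A beat is rejected when it falls outside ``abs_bounds`` or deviates from
    the median of the last :data:`FILTER_WINDOW` output beats by more than
    ``rel_tol`` (a fraction of that median).  Rejected beats are replaced by
    the running median, so the series keeps its length and the filter is
    idempotent.  The very first beat is checked against ``abs_bounds`` only
    (there is no local reference yet); an out-of-bounds first beat is
    replaced by the median of all in-bounds beats.
    """
    if not (0 < rel_tol < 1):
        raise ValueError("rel_tol must lie strictly between 0 and 1")
    lo, hi = abs_bounds
    x = series.intervals
    in_bounds = (x >= lo) & (x <= hi)
    if not in_bounds.any():
        raise DegenerateInputError(
            f"{series.record_id}: every beat lies outside {abs_bounds}")
    fallback = float(np.median(x[in_bounds]))

    out = np.empty_like(x)
    window: deque[float] = deque(maxlen=FILTER_WINDOW)
    n_replaced = 0
    for i, v in enumerate(x):
        if window:
            ref = float(np.median(window))
            bad = not (lo <= v <= hi) or abs(v - ref) > rel_tol * ref
        else:
            ref = fallback
            bad = not (lo <= v <= hi)
        if bad:
            out[i] = ref
            n_replaced += 1
        else:
            out[i] = v
        window.append(out[i])
    return replace(series, intervals=out,
                   n_filtered=series.n_filtered + n_replaced)


_SEGMENT_COLUMNS = ["record_id", "start", "end", "L", "mu_ms", "var_ms2"]


def write_segment_table(result, path, record_id: Optional[str] = None) -> None:
    """Write a segmentation result as a TSV table, one row per segment.

    Columns: ``record_id, start, end, L, mu_ms, var_ms2`` with 0-based
    half-open ``[start, end)`` spans, sorted by ``start``.  Floats are
    written with ``repr`` precision so a round-trip read is exact.
    """
    segments = getattr(result, "segments", result)
    if not segments:
        raise EmptyInputError("cannot write an empty segment table")
    rid = record_id or getattr(result, "record_id", "record")
    rows = [
        (rid, s.start, s.end, s.length, repr(float(s.mu)), repr(float(s.var)))
        for s in sorted(segments, key=lambda s: s.start)
    ]
    df = pd.DataFrame(rows, columns=_SEGMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_segment_table(path) -> pd.DataFrame:
    """Read a TSV segment table back into a DataFrame (exact floats)."""
    df = pd.read_csv(path, sep="\t", dtype={"record_id": str},
                     float_precision="round_trip")
    missing = set(_SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise RRParseError(path, 1, f"missing columns {sorted(missing)}")
    return df.astype({"start": int, "end": int, "L": int,
                      "mu_ms": float, "var_ms2": float})
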