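"""Monte-Carlo calibration of the critical curve for the maximal KS statistic.

The significance gate of the segmentation compares the observed maximal
weighted KS statistic D^max of a patch of length n against the 1 - alpha
quantile of D^max over i.i.d. sequences of the same length.  That null
quantile is estimated here by simulation (standard-normal draws; the
statistic is distribution-free for continuous data) on a geometric grid
of lengths and summarised by the three-parameter law

    q(n) = a * (ln n - b)^c.

The law bends sharply only near n ~ e^b, so grids confined to large n
leave b (and through it a and c) poorly identified.  The default grid
therefore starts at n = 16 -- far below the smallest patch the default
segmentation can test, and close enough to e^b to pin the bend -- and the
replicate schedule spends more draws at small n, where a scan is almost
free, keeping the quantile standard errors roughly balanced in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from ._kernels import scan_best
from .core import CriticalCurve
from .exceptions import CurveFitError, InsufficientDataError

__all__ = [
    "NullSample",
    "sample_dmax_null",
    "critical_quantile",
    "quantile_standard_error",
    "fit_critical_curve",
    "calibrate",
    "CriticalCurveCalibrator",
    "DEFAULT_N_GRID",
    "default_replicates",
]

#: Default calibration grid of sequence lengths (geometric, factor 2).
DEFAULT_N_GRID = (16, 32, 64, 128, 256, 512, 1024, 2048, 4096, 8192)

#: Baseline number of replicates at the large-n end of the grid.
DEFAULT_REPS = 2000


def default_replicates(n: int, base: int = DEFAULT_REPS) -> int:
    """Replicate schedule: ``base`` draws for n >= 1024, inflated up to
    8x for smaller n (cost per scan falls as n^2, precision need rises)."""
    return int(min(8 * base, base * max(1, 1024 // n)))


@dataclass(frozen=True)
class NullSample:
    """Draws of D^max for i.i.d. sequences of one length ``n``."""

    n: int
    dmax_values: np.ndarray
    seed: int

    def __post_init__(self):
        vals = np.asarray(self.dmax_values, dtype=np.float64)
        if vals.size < 1 or np.any(vals < 0):
            raise ValueError("dmax_values must be non-empty and non-negative")
        object.__setattr__(self, "dmax_values", vals)


def sample_dmax_null(n: int, reps: int, min_side: int = 2,
                     seed: int = 0) -> NullSample:
    """Draw ``reps`` values of D^max from i.i.d. N(0,1) sequences of length n."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n < 2 * min_side:
        raise InsufficientDataError(
            f"n={n} too small for min_side={min_side}")
    rng = np.random.default_rng(seed)
    out = np.empty(reps, dtype=np.float64)
    for i in range(reps):
        x = rng.standard_normal(n)
        out[i] = scan_best(x, min_side)[2]
    return NullSample(n=n, dmax_values=out, seed=seed)


def critical_quantile(sample: NullSample, p0: float) -> float:
    """Empirical p0-quantile of the null D^max draws (linear interpolation)."""
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly between 0 and 1")
    return float(np.quantile(sample.dmax_values, p0))


def quantile_standard_error(sample: NullSample, p0: float) -> float:
    """Standard error of the empirical quantile via the binomial bracket.

    Order statistics at ranks R*p0 +- sqrt(R p0 (1-p0)) bracket one
    standard deviation of the quantile estimator; half their spread is a
    serviceable SE for weighting the curve fit.  At small n the statistic
    is discrete and the bracket can collapse onto a single atom, which
    would claim spurious precision: the SE is floored at half the local
    spacing between neighbouring atoms around the quantile.
    """
    vals = np.sort(sample.dmax_values)
    r = vals.size
    half = np.sqrt(r * p0 * (1.0 - p0))
    lo = int(np.clip(np.floor(r * p0 - half), 0, r - 1))
    hi = int(np.clip(np.ceil(r * p0 + half), 0, r - 1))
    se = (vals[hi] - vals[lo]) / 2.0
    # discreteness floor: half the gap between the nearest distinct values
    # below and above the quantile
    q = float(np.quantile(vals, p0))
    uniq = np.unique(vals)
    k = int(np.searchsorted(uniq, q))
    below = uniq[max(k - 1, 0)]
    above = uniq[min(k + 1, uniq.size - 1)]
    atom_gap = (above - below) / 2.0
    return float(max(se, atom_gap / 2.0, 1e-6))


def _curve_model(n, a, b, c):
    return a * (np.log(n) - b) ** c


def fit_critical_curve(ns: Sequence[int], quantiles: Sequence[float],
                       p0: float, sigma: Optional[Sequence[float]] = None,
                       ) -> CriticalCurve:
    """Weighted nonlinear least squares of q(n) = a(ln n - b)^c.

    Requires at least four distinct lengths spanning 1.5 decades.  The
    constraint b < ln(min n) keeps the model real on the grid; ``sigma``
    supplies per-point quantile standard errors for weighting.
    """
    ns = np.asarray(ns, dtype=np.float64)
    qs = np.asarray(quantiles, dtype=np.float64)
    if ns.size != qs.size:
        raise ValueError("ns and quantiles must have equal length")
    if np.unique(ns).size < 4:
        raise InsufficientDataError("need >= 4 distinct sequence lengths")
    if np.log10(ns.max() / ns.min()) < 1.5:
        raise InsufficientDataError(
            "calibration lengths must span at least 1.5 decades")
    if np.any(qs <= 0):
        raise ValueError("quantiles must be positive")
    b_max = float(np.log(ns.min())) - 1e-6
    try:
        popt, _ = curve_fit(
            _curve_model, ns, qs,
            p0=(1.5, min(1.8, b_max - 0.1), 0.15),
            sigma=None if sigma is None else np.asarray(sigma, float),
            absolute_sigma=sigma is not None,
            bounds=([1e-6, -20.0, 1e-3], [20.0, b_max, 2.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise CurveFitError(f"critical-curve fit did not converge: {exc}",
                            residuals=qs - _curve_model(ns, 1.5, 1.8, 0.15))
    a, b, c = (float(v) for v in popt)
    rss = float(np.sum((qs - _curve_model(ns, a, b, c)) ** 2))
    return CriticalCurve(a=a, b=b, c=c, p0=p0, rss=rss)


def calibrate(p0: float = 0.95, n_grid: Sequence[int] = DEFAULT_N_GRID,
              reps: Optional[int] = None, min_side: int = 2, seed: int = 0,
              ) -> tuple[CriticalCurve, pd.DataFrame]:
    """Full calibration: simulate, take quantiles, fit the curve.

    ``reps`` sets the baseline replicate count at large n (default 2000);
    smaller lengths receive proportionally more draws, see
    :func:`default_replicates`.  Returns the fitted curve and a table with
    one row per grid length (n, reps, quantile, standard error).
    """
    base = reps if reps is not None else DEFAULT_REPS
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(len(n_grid))]
    rows = []
    for n, s in zip(n_grid, child_seeds):
        r = default_replicates(int(n), base)
        sample = sample_dmax_null(int(n), r, min_side=min_side, seed=s)
        q = critical_quantile(sample, p0)
        se = quantile_standard_error(sample, p0)
        rows.append({"n": int(n), "reps": r, "quantile": q, "se": se})
    table = pd.DataFrame(rows)
    curve = fit_critical_curve(table["n"], table["quantile"], p0,
                               sigma=table["se"])
    return curve, table


class CriticalCurveCalibrator(BaseEstimator):
    """Estimator interface to :func:`calibrate`.

    ``fit`` ignores its arguments (the null model needs no data) and runs
    the Monte-Carlo calibration with the configured parameters.

    Attributes
    ----------
    curve_ : CriticalCurve
    a_, b_, c_ : float fitted coefficients
    table_ : DataFrame of per-length quantiles and standard errors
    """

    def __init__(self, p0: float = 0.95, n_grid: Sequence[int] = DEFAULT_N_GRID,
                 reps: Optional[int] = None, min_side: int = 2,
                 random_state: int = 0):
        self.p0 = p0
        self.n_grid = n_grid
        self.reps = reps
        self.min_side = min_side
        self.random_state = random_state

    def fit(self, X=None, y=None):
        self.curve_, self.table_ = calibrate(
            p0=self.p0, n_grid=self.n_grid, reps=self.reps,
            min_side=self.min_side, seed=self.random_state)
        self.a_ = self.curve_.a
        self.b_ = self.curve_.b
        self.c_ = self.curve_.c
        return self
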