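"""Classic time- and frequency-domain HRV measures.

These are the standard quantities the segment statistics are correlated
against: sdNN (standard deviation of the RR series), pNN50 (percentage of
successive differences above 50 ms) and the normalised very-low-frequency
power VLF/P.  The spectrum of the unevenly sampled tachogram is estimated
with a Lomb least-squares periodogram on the beat-time axis, which avoids
interpolating the series onto a regular grid (interpolation leaks power
into exactly the VLF band under study).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .exceptions import InsufficientDataError

__all__ = ["sdnn", "pnn50", "vlf_fraction", "SpectralSummary"]

#: Band edges in Hz: VLF lower, VLF upper, total-band upper.
VLF_LOW_HZ = 0.0033
VLF_HIGH_HZ = 0.03
TOTAL_HIGH_HZ = 0.4

#: Minimum record duration for a meaningful VLF estimate, seconds.
MIN_DURATION_S = 600.0


@dataclass(frozen=True)
class SpectralSummary:
    """VLF and total power of the RR tachogram, ms^2 (periodogram units)."""

    vlf_power: float
    total_power: float

    @property
    def vlf_fraction(self) -> float:
        return self.vlf_power / self.total_power if self.total_power > 0 else 0.0


def sdnn(x) -> float:
    """Sample standard deviation of the RR series, ms."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise InsufficientDataError("sdNN needs at least two intervals")
    return float(np.std(x, ddof=1))


def pnn50(x, threshold_ms: float = 50.0) -> float:
    """Percentage of successive RR differences exceeding 50 ms."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise InsufficientDataError("pNN50 needs at least two intervals")
    return 100.0 * float(np.mean(np.abs(np.diff(x)) > threshold_ms))


def vlf_fraction(x, vlf_low: float = VLF_LOW_HZ, vlf_high: float = VLF_HIGH_HZ,
                 total_high: float = TOTAL_HIGH_HZ, oversample: int = 4,
                 ) -> SpectralSummary:
    """Fraction of tachogram power in the VLF band [vlf_low, vlf_high] Hz.

    The RR values are placed at their beat times (cumulative sums of the
    intervals, seconds), mean-removed, and a Lomb periodogram is evaluated
    on a grid of spacing 1/(oversample * T) covering [vlf_low, total_high].
    Both band powers are sums of the periodogram over their grid points,
    so the fraction is a pure power ratio.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    t = np.cumsum(x) / 1000.0  # beat times, s
    span = t[-1] - t[0] if x.size > 1 else 0.0
    if span < MIN_DURATION_S:
        raise InsufficientDataError(
            f"record spans {span:.0f} s; VLF needs >= {MIN_DURATION_S:.0f} s")
    y = x - x.mean()
    df = 1.0 / (oversample * span)
    freqs = np.arange(vlf_low, total_high + df / 2, df)
    power = lombscargle(t, y, 2.0 * np.pi * freqs)
    vlf = float(power[freqs <= vlf_high].sum())
    total = float(power.sum())
    return SpectralSummary(vlf_power=vlf, total_power=total)
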