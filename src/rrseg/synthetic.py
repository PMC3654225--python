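"""Synthetic piecewise-stationary RR series with known ground truth.

The generator emulates the statistical structure a 24 h heart-beat record
fragments into: segment lengths drawn from a two-exponential mixture, a
mean RR level that moves by Laplace-distributed jumps at segment
boundaries, per-segment variances spread log-normally, and stationary
AR(1) noise inside each segment.  Nothing physiological beyond that is
modelled (no respiratory sinus arrhythmia, no circadian ramp); the point
is a series whose change points and per-segment moments are known, so
every stage of the analysis can be validated without recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import RRSegError
from .series import RRSeries

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_piecewise_rr",
    "generate_reference",
    "generate_cohort",
    "sample_segment_variances",
    "healthy_spec",
    "chf_like_spec",
]

#: Clipping bounds of generated intervals, ms (same as the filter bounds).
CLIP_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic record.

    length_dist : (A, L1, L2, l0)
        Two-exponential mixture of segment lengths (beats): with
        probability A the length is l0 + Exp(L1), otherwise l0 + Exp(L2).
    base_mean_ms : float
        Mean RR level the record starts at.
    jump_scale_ms : float
        Scale of the Laplace-distributed change of the segment mean.
    var_dist : (m, s)
        Mean and sd of log10 of the per-segment variance (ms^2).
    ar1 : float
        Lag-1 autocorrelation of the within-segment noise, in [0, 0.9].
    """

    n_beats: int = 20_000
    length_dist: Tuple[float, float, float, float] = (0.6, 40.0, 400.0, 30.0)
    base_mean_ms: float = 900.0
    jump_scale_ms: float = 30.0
    var_dist: Tuple[float, float] = (2.7, 0.45)
    ar1: float = 0.2
    seed: int = 0

    def __post_init__(self):
        A, L1, L2, l0 = self.length_dist
        if not (0.0 <= A <= 1.0) or L1 <= 0 or L2 <= 0:
            raise ValueError("length mixture requires 0 <= A <= 1, scales > 0")
        if l0 < 2 or l0 > self.n_beats:
            raise RRSegError(
                f"l0={l0} infeasible for a record of {self.n_beats} beats")
        if not (0.0 <= self.ar1 <= 0.9):
            raise ValueError("ar1 must lie in [0, 0.9]")
        if self.base_mean_ms <= 0 or self.jump_scale_ms < 0:
            raise ValueError("scales must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic record.

    ``change_points`` are the 0-based start indices of every segment but
    the first (i.e. the interior boundaries); means/vars are the planted
    parameters, not the realised sample moments.
    """

    change_points: np.ndarray
    segment_means: np.ndarray
    segment_vars: np.ndarray
    n_beats: int

    def __post_init__(self):
        cps = np.asarray(self.change_points, dtype=int)
        if cps.size and (np.any(np.diff(cps) <= 0) or cps[0] <= 0
                         or cps[-1] >= self.n_beats):
            raise ValueError("change points must be strictly increasing "
                             "inside (0, n_beats)")
        if len(self.segment_means) != cps.size + 1:
            raise ValueError("need one mean and variance per segment")
        object.__setattr__(self, "change_points", cps)
        object.__setattr__(self, "segment_means",
                           np.asarray(self.segment_means, dtype=np.float64))
        object.__setattr__(self, "segment_vars",
                           np.asarray(self.segment_vars, dtype=np.float64))

    @property
    def boundaries(self) -> np.ndarray:
        """All boundaries including 0 and n_beats."""
        return np.concatenate([[0], self.change_points, [self.n_beats]])


def _draw_lengths(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    A, L1, L2, l0 = spec.length_dist
    lengths: List[int] = []
    total = 0
    while total < spec.n_beats:
        scale = L1 if rng.random() < A else L2
        L = int(round(l0 + rng.exponential(scale)))
        lengths.append(L)
        total += L
    lengths[-1] -= total - spec.n_beats
    if lengths[-1] < 1:  # merge a degenerate remainder into its neighbour
        lengths[-2] += lengths[-1]
        lengths.pop()
    return np.asarray(lengths, dtype=int)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float,
               phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.normal(0.0, sd, n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i - 1]
    return out


def generate_piecewise_rr(spec: SyntheticSpec,
                          record_id: str = "synthetic",
                          group_label: Optional[str] = None,
                          ) -> tuple[RRSeries, GroundTruth]:
    """Draw one synthetic RR record and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    lengths = _draw_lengths(rng, spec)
    k = lengths.size
    jumps = rng.laplace(0.0, spec.jump_scale_ms, k) if spec.jump_scale_ms else np.zeros(k)
    jumps[0] = 0.0
    means = spec.base_mean_ms + np.cumsum(jumps)
    # keep the level physiological: reflect into the clip band interior
    lo, hi = CLIP_MS[0] + 50.0, CLIP_MS[1] - 50.0
    means = lo + np.abs((means - lo) % (2 * (hi - lo)))
    means = np.where(means > hi, 2 * hi - lo - means + lo, means)
    m, s = spec.var_dist
    variances = 10.0 ** rng.normal(m, s, k)
    chunks = [
        mu + _ar1_noise(rng, int(L), float(np.sqrt(v)), spec.ar1)
        for L, mu, v in zip(lengths, means, variances)
    ]
    x = np.clip(np.concatenate(chunks), *CLIP_MS)
    truth = GroundTruth(change_points=np.cumsum(lengths)[:-1],
                        segment_means=means, segment_vars=variances,
                        n_beats=spec.n_beats)
    series = RRSeries(x, record_id=record_id, group_label=group_label)
    return series, truth


def generate_reference(process: str, n: int, seed: int = 0) -> np.ndarray:
    """Reference noise: ``"white"`` (i.i.d. N(0,1)) or ``"random_walk"``
    (its cumulative sum).  Anchors for the scaling exponent xi."""
    if n < 100:
        raise RRSegError("reference processes need n >= 100")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    if process == "white":
        return white
    if process == "random_walk":
        return np.cumsum(white)
    raise ValueError(f"unknown process {process!r}")


def sample_segment_variances(m: float, s: float, size: int,
                             seed: int = 0) -> np.ndarray:
    """Per-segment variances with log10 sigma^2 ~ Normal(m, s), ms^2."""
    rng = np.random.default_rng(seed)
    return 10.0 ** rng.normal(m, s, size)


def healthy_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Study conditions of a healthy-like synthetic subject."""
    return replace(SyntheticSpec(seed=seed), **overrides)


def chf_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """CHF-like conditions: variance scale lowered by 0.5 decades and
    mean jumps reduced, mimicking diminished non-stationarity."""
    base = SyntheticSpec(seed=seed)
    params = dict(
        var_dist=(base.var_dist[0] - 0.5, base.var_dist[1]),
        jump_scale_ms=base.jump_scale_ms / 2.0,
    )
    params.update(overrides)
    return replace(base, **params)


def generate_cohort(specs: Dict[str, SyntheticSpec], n_subjects: int,
                    seed: int = 0,
                    ) -> List[tuple[RRSeries, GroundTruth]]:
    """Independent subjects per group with group-specific parameters.

    Each subject gets a child seed spawned from ``seed``; the input
    specs' own seeds are ignored.
    """
    if len(specs) < 2:
        raise ValueError("a cohort needs at least two groups")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * n_subjects)
    out = []
    i = 0
    for group, spec in specs.items():
        for j in range(n_subjects):
            child_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
            i += 1
            subj_spec = replace(spec, seed=child_seed)
            series, truth = generate_piecewise_rr(
                subj_spec, record_id=f"{group}-{j:02d}", group_label=group)
            out.append((series, truth))
    return out
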