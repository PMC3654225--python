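# Methods

## Model and procedure

A beat-to-beat (RR) interval series is modelled as piecewise stationary:
an unknown number of patches, within each of which the intervals are
draws from one distribution, with abrupt distributional changes at the
patch boundaries. Segmentation proceeds recursively. For the patch under
examination, every admissible cut position p is scored with the weighted
two-sample Kolmogorov–Smirnov statistic

    D(p) = D_KS(p) * (1/n_L + 1/n_R)^(-1/2),

where D_KS is the sup-distance between the empirical CDFs of the two
sides, evaluated on the union of observed values so that ties are exact.
The size weighting makes D comparable across asymmetric cuts. The
maximal-D cut is accepted iff

1. D^max exceeds the critical value D_crit(n) = a(ln n − b)^c for the
   current patch length n (significance gate at level α = 1 − P0), and
2. both resulting parts have at least l_min beats (minimum-length gate).

If the significant maximal cut fails the length gate the patch is left
uncut; no second-best cut is searched, which is the conservative reading
of the procedure and keeps the null calibration interpretable. Recursion
is depth-first, left patch first, and stops on patches shorter than
2·l_min. Defaults: P0 = 0.95, l_min = 30 beats (half a period of the
0.03 Hz upper VLF edge at ~1 beat/s), scan admissibility min_side = 2.

Because the two-sample KS statistic is distribution-free for continuous
i.i.d. data, one critical curve serves any continuous within-patch
marginal; the tests exploit this with uniform as well as Gaussian nulls.

## Critical-curve calibration

The null quantile of D^max is estimated by simulation: for each length n
on a geometric grid, i.i.d. N(0,1) sequences are scanned and the empirical
P0-quantile of D^max recorded (linear-interpolation convention), then
a(ln n − b)^c is fitted by weighted nonlinear least squares
(initialisation (1.5, 1.8, 0.15), constraint b < ln min n).

Design choices that matter here:

* **Grid.** n ∈ {16, 32, …, 8192}. The law bends appreciably only near
  n ~ e^b ≈ 6, so grids confined to large n leave b — and through the
  strong (a, b, c) collinearity all three coefficients — essentially
  unidentified: a synthetic perturbation study showed that with
  quantile noise at the 2000-replicate level, a fit on n ≥ 128 alone
  scatters b over more than ±1.5. Including small lengths pins the bend;
  they are also where the recursion actually applies the threshold
  (patches as short as 2·l_min = 60).
* **Replicates.** 2000 per length for n ≥ 1024, inflated up to 16000 at
  the small end, where one scan costs O(n²) ~ microseconds; this roughly
  balances the quantile standard errors across the grid.
* **Weights.** Per-point quantile SEs from the binomial order-statistic
  bracket. At small n the D^max distribution is discrete; when the
  bracket collapses onto a single atom the SE is floored at half the
  local atom spacing, otherwise a near-zero weight would let small-n
  discreteness steer the fit.
* The fitted coefficients at P0 = 0.95 agree with the published
  reference values (1.52, 1.80, 0.14) shipped as the default curve; the
  false-cut closure test (fraction of fresh i.i.d. sequences receiving
  any cut ≈ α) ties the calibration back to the segmentation.

## Segment statistics

Per record: segment lengths L, means μ, population variances σ²
(denominator L, not L−1). The piecewise-constant trend of segment means,
subtracted from the series, yields the detrended series RR*; because each
segment's residual sums to zero, the population variances decompose
exactly, σ²(x) = σ²_T + σ²_*, and the tests assert this to 1e-9 relative.
σ²_T is the variance of the trend *series* (length-weighted), not of the
unweighted list of segment means — the reading that makes the identity
exact. %μ50 is the percentage of consecutive-segment mean jumps above
50 ms; L_{>300} counts segments strictly longer than 300 beats.

Distribution fits:

* **Length tail.** The empirical complementary CDF (≥ convention, so the
  model equals 1 at the left edge l0) is fitted with
  A·exp(−(L−l0)/L1) + (1−A)·exp(−(L−l0)/L2), A ∈ [0,1], L1 ≤ L2 restored
  by relabelling; initialisation from a two-piece log-linear split at the
  empirical median. Fitting the CCDF rather than a binned PDF avoids
  binning noise exactly where the long scale L2 lives.
* **Variance PDF.** Histogram of log10 σ² (25 equal-width bins by
  default, matching the few-hundred-segment scale of a 24 h record),
  density per unit σ², ordinary least squares of log10 PDF on
  [log10 σ²]² and log10 σ² over non-empty bins. For log10 σ² ~ N(m, s)
  the parabola is exact with c2 = −1/(2 s² ln 10), c1 = m/(s² ln 10) − 1,
  c0 = −m²/(2 s² ln 10) − log10(s·ln 10·√(2π)); the tests recover these
  closed forms from 20 000 draws within 10 %. The intercept c0 (γ) is the
  cohort discriminator.
* **Variance–length scaling.** Mean segment variance per logarithmic
  length bin (geometric-mean L per bin, bins with ≥ 5 segments), slope ξ
  of log10⟨σ²(L)⟩ against log10 L over all usable bins; the fit range is
  exposed because different records populate different length ranges.

### Interpreting ξ and its anchors

For *fixed* windows, white noise has window variance independent of L
(ξ = 0) and a random walk has window variance ∝ L (ξ = 1). The package
validates its ⟨σ²(L)⟩ machinery against these two analytic anchors using
`windowed_segments` (tiling the reference process with windows of
log-spaced lengths), reproducing ξ ≈ 0 and ξ ≈ 1.

Segmentation-derived patches are different in one important way: a patch
survives only if it shows no significant internal distribution change, so
long surviving patches of a random walk are atypically flat. Empirically,
segmenting a pure 30k–50k-step random walk yields ξ ≈ 0.6 — the regime
reported for failing hearts whose dynamics are random-walk dominated —
rather than the naive 1. This selection effect is intrinsic to the
method, is covered by a characterisation test (0.35 ≤ ξ ≤ 0.85), and
should be kept in mind when comparing ξ across pipelines.

## Classic HRV measures

sdNN is the sample standard deviation of the filtered series; pNN50 the
percentage of successive differences above 50 ms. VLF/P places the RR
values at their beat times (cumulative interval sums), removes the mean,
and evaluates a Lomb least-squares periodogram on a grid of spacing
1/(4T) over [0.0033, 0.4] Hz; VLF power is the band sum over
[0.0033, 0.03] Hz (0.03 Hz upper edge; all four edges configurable) and
the fraction is a pure power ratio. The Lomb estimator avoids resampling
the unevenly spaced tachogram, which would leak interpolation power into
the VLF band. A flat-spectrum check (white tachogram → fraction ≈
bandwidth ratio 0.067) validates the normalisation.

## Cohort comparisons

Mann–Whitney U with midrank ties; exact two-sided p by enumeration of all
label assignments when the pooled sample has ≤ 12 observations (valid
under ties), otherwise the normal approximation with tie and continuity
corrections — at 15–18 subjects per group the approximation error is well
below the decision levels used (the tests bound it at 0.02 for two
groups of five). Correlations are Pearson by default with a Spearman
alternative. No multiple-testing correction is applied across measures;
none is silently added.

## Ectopic-beat filter

Ectopic beats and annotation artifacts are replaced, not deleted, so
segment indices stay aligned with beat numbers: a beat is rejected if it
leaves [300, 2000] ms or deviates by more than 20 % from the median of
the last 11 output beats, and is replaced by that running median. Feeding
outputs back into the reference window makes the filter idempotent. The
first beat has no local reference and is checked against the absolute
bounds only. This is a standard adaptive HRV preprocessing rule chosen
for testability; cohort-level statistics that depend on filtering details
may shift under other filters.

## Synthetic generator

`SyntheticSpec` defaults describe one "healthy-like" study condition:
20 000 beats (a desk-scale stand-in for ~10⁵-beat 24 h records), segment
lengths from the mixture (A, L1, L2, l0) = (0.6, 40, 400, 30) beats,
base level 900 ms, Laplace mean jumps of scale 30 ms, per-segment
variances with log10 σ² ~ N(2.7, 0.45) (median σ ≈ 22 ms), within-segment
AR(1) noise with φ = 0.2, intervals clipped to 300–2000 ms. The CHF-like
variant lowers the variance scale by 0.5 decades and halves the jump
scale, mimicking diminished non-stationarity. Laplace jumps and
log-normal variances are simple heavy-ish-tailed laws with closed-form
audits; the generator targets statistical structure only — no
respiratory sinus arrhythmia, no circadian trend — so passing tests show
the pipeline recovers planted distributional structure, not that it
models physiology.

The cohort power analysis (γ Mann–Whitney between 15 + 15 subjects with
the −0.5-decade variance shift, 300 segment variances per subject, 100
replicates) draws per-subject variances directly from the generator's
variance law; a full generate → filter → segment → summarise cohort run
is exercised separately at 6 000-beat scale. Change-point recovery and
false-cut-rate properties use 2 000–5 000-beat records, and the
segmentation-conditioned scaling test a 30 000-step walk; these problem
sizes keep the whole suite at desk scale while leaving every estimate's
sampling error well inside the asserted tolerances.

## Numerical notes

* The scan is an O(n²) incremental integer update of the unnormalised
  ECDF difference over value ranks (numba-compiled when available, with
  a vectorised numpy fallback); exact for ties, ~45 ms at n = 8192.
  Equality with an independent scipy-based brute-force maximiser is
  property-tested.
* Tie-break at equal D: smallest cut index; segmentation is fully
  deterministic given the series, parameters and curve.
* Degenerate inputs raise typed errors (`EmptyInputError`,
  `DegenerateInputError`, `InsufficientDataError`,
  `UndefinedStatisticError`) rather than returning NaNs.
* All randomness flows through `numpy.random.default_rng` seeds;
  cohort/subject seeds are spawned via `SeedSequence`.

## Known limitations

* The recursive test controls the per-scan false-cut rate at α, not a
  family-wise rate: on a correctly split record, each stationary patch
  still receives a spurious cut with probability ≈ α (slightly less
  after the length gate). Perfect two-segment recovery of a single step
  therefore occurs in ≈ 91–93 % of realisations at P0 = 0.95, not 95 %.
* Short records (< ~2000 beats) give few segments and unstable
  distribution fits; the method is intended for long (hours-scale)
  recordings.
* σ²_T here is length-weighted; an unweighted per-segment-mean variance
  would differ on records with very uneven segment lengths.
* The VLF estimator dialect (Lomb on beat time, band edges) affects
  magnitudes of VLF/P; correlation signs against L_{>300} are expected to
  be robust, magnitudes are not guaranteed.
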