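# rrseg

Nonparametric Kolmogorov–Smirnov segmentation of heart-beat (RR) interval
series, with the segment-based non-stationarity statistics used to study
aging and congestive heart failure in 24 h heart-rate-variability (HRV)
recordings.

A long RR record is not stationary: posture, sleep stages, respiration and
autonomic regulation shift its level and spread on many time scales.
`rrseg` splits a series into patches that are internally stationary *in
distribution* and then treats the patch population — lengths, means,
variances, jumps between means — as the object of analysis. It is aimed at
researchers working with beat-annotated Holter recordings (e.g. PhysioNet
RR exports) and at methodologists who want a calibrated, testable
change-point pipeline for physiological series.

## Method

For a candidate cut of a patch of length *n* into left/right parts of
sizes *n*<sub>L</sub>, *n*<sub>R</sub>, the weighted two-sample KS statistic is

D = D<sub>KS</sub> · (1/n<sub>L</sub> + 1/n<sub>R</sub>)<sup>−1/2</sup>,

where D<sub>KS</sub> is the sup-distance between the two empirical CDFs. The cut
maximising D is accepted iff D exceeds the Monte-Carlo critical value

D<sup>max</sup><sub>crit</sub>(n) = a (ln n − b)<sup>c</sup>
 (a, b, c) ≈ (1.52, 1.80, 0.14) at P₀ = 0.95,

the 1−α quantile of D<sup>max</sup> over i.i.d. sequences (distribution-free for
continuous data), and both parts are at least ℓ₀ = 30 beats long; the
procedure recurses, left patch first. On the resulting segments the
package computes %μ50 (fraction of consecutive segment-mean jumps > 50 ms),
the long-segment count L<sub>>300</sub>, the exact variance decomposition
σ²(x) = σ²_T + σ²_⋆ (trend vs detrended), two-exponential fits of the
segment-length tail, quadratic log-PDF fits of the variance distribution
(the γ intercept discriminates cohorts), the variance–length scaling
exponent ξ, classic HRV measures (sdNN, pNN50, VLF/P via a Lomb
periodogram), and Mann–Whitney cohort comparisons. A seeded synthetic
generator produces piecewise-stationary RR records with known change
points for validation end to end.

## Worked example

```python
import numpy as np
import rrseg

# a synthetic 20,000-beat record with planted structure
series, truth = rrseg.generate_piecewise_rr(rrseg.SyntheticSpec(seed=42))
filtered = rrseg.filter_ectopic(series)

seg = rrseg.KSSegmenter(p0=0.95, l_min=30).fit(filtered.intervals)
summary = rrseg.summarize_record(filtered.intervals, seg.result_)
print(f"{seg.n_segments_} segments over {len(filtered)} beats")
print(f"pct_mu50 = {summary.pct_mu50:.1f}%  L>300 = {summary.n_long}")
print(f"var split: total {summary.var_total:.0f} = "
      f"trend {summary.var_trend:.0f} + detrended {summary.var_detrended:.0f} ms^2")
```

prints

```
88 segments over 20000 beats
pct_mu50 = 19.5%  L>300 = 18
var split: total 48294 = trend 47598 + detrended 696 ms^2
```

88 stationary patches were found; 19.5 % of the jumps between successive
patch means exceed 50 ms, 18 patches are longer than ~5 minutes, and of
the total population variance of 48294 ms², 47598 ms² lives in the
piecewise-constant trend of patch means (this record's level wanders far
more than it fluctuates locally) and 696 ms² in the residual fluctuation
inside patches — the two parts add exactly.

The same pipeline is available from the shell:

```bash
rrseg simulate --subjects 1 --seed 42 -o sim/
rrseg segment sim/sim-00.rr.txt -o segments.tsv
rrseg metrics segments.tsv --rr sim/sim-00.rr.txt -o summary.json
rrseg classic sim/sim-00.rr.txt -o classic.json
```

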