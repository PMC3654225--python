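"""Synthetic generator: ground-truth consistency and pipeline closure."""

import numpy as np
import pytest

import rrseg
from rrseg.exceptions import RRSegError
from rrseg.fits import fit_var_pdf
from rrseg.compare import mann_whitney_u
from rrseg.metrics import summarize_record
from rrseg.synthetic import (
    SyntheticSpec,
    chf_like_spec,
    generate_cohort,
    generate_piecewise_rr,
    generate_reference,
    healthy_spec,
    sample_segment_variances,
)


class TestGenerator:
    def test_reproducible_given_seed(self):
        s1, t1 = generate_piecewise_rr(SyntheticSpec(n_beats=3000, seed=9))
        s2, t2 = generate_piecewise_rr(SyntheticSpec(n_beats=3000, seed=9))
        assert np.array_equal(s1.intervals, s2.intervals)
        assert np.array_equal(t1.change_points, t2.change_points)

    def test_ground_truth_bookkeeping(self):
        series, truth = generate_piecewise_rr(SyntheticSpec(n_beats=5000, seed=1))
        assert len(series) == 5000
        assert truth.boundaries[0] == 0 and truth.boundaries[-1] == 5000
        assert truth.segment_means.size == truth.change_points.size + 1
        assert truth.segment_vars.size == truth.segment_means.size

    def test_sample_moments_match_truth(self):
        # with white within-segment noise the realised per-segment moments
        # must sit within sampling error of the planted parameters
        spec = SyntheticSpec(n_beats=20_000, ar1=0.0, seed=4)
        series, truth = generate_piecewise_rr(spec)
        x = series.intervals
        bounds = truth.boundaries
        n_checked = 0
        for k in range(truth.segment_means.size):
            lo, hi = bounds[k], bounds[k + 1]
            L = hi - lo
            if L < 30:
                continue
            mu, var = truth.segment_means[k], truth.segment_vars[k]
            chunk = x[lo:hi]
            if chunk.min() <= 305 or chunk.max() >= 1995:
                continue  # clipped segments are biased by construction
            se_mean = np.sqrt(var / L)
            assert abs(chunk.mean() - mu) < 4 * se_mean
            se_var = var * np.sqrt(2.0 / (L - 1))
            assert abs(chunk.var(ddof=1) - var) < 5 * se_var
            n_checked += 1
        assert n_checked >= 10

    def test_infeasible_spec_rejected(self):
        with pytest.raises(RRSegError):
            SyntheticSpec(n_beats=20, length_dist=(0.6, 40, 400, 30))

    def test_reference_processes(self):
        w = generate_reference("white", 5000, seed=0)
        rw = generate_reference("random_walk", 5000, seed=0)
        assert np.allclose(np.diff(rw), w[1:])
        assert abs(w.mean()) < 0.1 and abs(w.std() - 1) < 0.05
        with pytest.raises(ValueError):
            generate_reference("pink", 5000)


class TestNullAndRecovery:
    def test_homogeneous_series_rarely_cut(self):
        # jump scale 0, ar1 0 reduces to an i.i.d. null: the cut rate
        # must be near alpha = 0.05
        spec = SyntheticSpec(n_beats=2000, jump_scale_ms=0.0, ar1=0.0,
                             length_dist=(1.0, 1e9, 1e9, 30))
        cut = 0
        n_rec = 120
        for seed in range(n_rec):
            series, _ = generate_piecewise_rr(
                SyntheticSpec(**{**spec.__dict__, "seed": seed}))
            cut += rrseg.segment(series.intervals).n_segments > 1
        assert cut / n_rec <= 0.12

    def test_high_snr_change_points_recovered(self):
        # large mean jumps over small within-segment noise: most planted
        # boundaries must be found within +-10 beats
        found, planted = 0, 0
        for seed in range(25):
            spec = SyntheticSpec(n_beats=5000, jump_scale_ms=200.0,
                                 var_dist=(2.0, 0.2), ar1=0.0, seed=seed)
            series, truth = generate_piecewise_rr(spec)
            res = rrseg.segment(series.intervals)
            cps = res.change_points
            for cp in truth.change_points:
                planted += 1
                if cps.size and np.min(np.abs(cps - cp)) <= 10:
                    found += 1
        assert found / planted >= 0.80


class TestCohort:
    def test_labels_and_counts_preserved(self):
        specs = {"H": healthy_spec(n_beats=2000), "C": chf_like_spec(n_beats=2000)}
        cohort = generate_cohort(specs, n_subjects=3, seed=11)
        assert len(cohort) == 6
        labels = [s.group_label for s, _ in cohort]
        assert labels.count("H") == 3 and labels.count("C") == 3
        assert len({s.record_id for s, _ in cohort}) == 6

    def test_identical_specs_reject_at_alpha(self):
        # null calibration of the gamma comparison: same variance law in
        # both groups must not separate much above the nominal level
        rejections = 0
        reps = 40
        for rep in range(reps):
            g1 = [fit_var_pdf(sample_segment_variances(2.7, 0.45, 300,
                                                       seed=rep * 61 + j)).c0
                  for j in range(15)]
            g2 = [fit_var_pdf(sample_segment_variances(2.7, 0.45, 300,
                                                       seed=10_000 + rep * 61 + j)).c0
                  for j in range(15)]
            rejections += mann_whitney_u(g1, g2).p_value < 0.05
        assert rejections / reps <= 0.20

    def test_pipeline_end_to_end_deterministic(self):
        # generate -> filter -> segment -> summarize twice; summaries match
        specs = {"H": healthy_spec(n_beats=6000), "C": chf_like_spec(n_beats=6000)}

        def run():
            out = []
            for series, _ in generate_cohort(specs, n_subjects=2, seed=3):
                filtered = rrseg.filter_ectopic(series)
                res = rrseg.segment(filtered.intervals,
                                    record_id=series.record_id)
                out.append(summarize_record(filtered.intervals, res,
                                            group_label=series.group_label))
            return out

        a, b = run(), run()
        for s1, s2 in zip(a, b):
            assert s1 == s2
        assert {s.group_label for s in a} == {"H", "C"}
        assert all(s.n_segments >= 2 for s in a)
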