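"""Moving averages, paired t, Shapiro–Wilk and the cohort summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neckcool import (
    SimulationProtocol,
    build_collar,
    build_network,
    compare_sim_to_experiment,
    moving_average,
    paired_t,
    run_protocol,
    shapiro_wilk,
    summarize_cohort,
    table1_records,
)
from neckcool.simulate import TemperatureTrace
from neckcool.stats import DegenerateSampleError
from neckcool.synthetic_data import CohortSpec, generate_cohort

# Oracle values computed with R 4.3.3 shapiro.test (Royston's algorithm),
# frozen here: (sample, W, p)
R_SHAPIRO_ORACLE = [
    (sps.norm.ppf((np.arange(1, 11) - 0.5) / 10), 0.9979773028, 0.9999970154),
    (np.array([1.0] * 9 + [100.0]), 0.3657206274, 1.003692814e-07),
    (np.array([2.3, 1.9, 3.1, 2.8, 2.2, 2.7, 3.0, 2.1, 2.6, 2.4, 1.8, 3.3]),
     0.9713190182, 0.9241188208),
    (np.array([36.0, 36.5, 36.8, 36.8]), 0.8412980230, 0.1992135896),
]


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(200, 36.5)
        assert np.array_equal(moving_average(x, 60.0), x)

    def test_window_of_one_sample_is_identity(self):
        x = np.sin(np.linspace(0, 3, 50))
        assert np.array_equal(moving_average(x, 1.0), x)

    def test_linear_ramp_passes_through_including_edges(self):
        x = np.arange(11.0)
        sm = moving_average(x, 3.0)
        assert np.allclose(sm, x, atol=1e-12)

    def test_commutes_with_affine_transforms(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        a, b = 2.5, -7.0
        assert np.allclose(moving_average(a * x + b, 60.0),
                           a * moving_average(x, 60.0) + b, atol=1e-10)

    def test_smooths_white_noise(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        assert moving_average(x, 60.0)[100:-100].std() < 0.3 * x.std()

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            moving_average([], 60.0)


class TestPairedT:
    def test_table1_brain_and_body_p_values(self):
        # printed per-animal cells reproduce the published p-values
        brain = paired_t([36.0, 36.5, 36.8, 36.8], [35.6, 35.9, 36.1, 36.4])
        assert brain[0] == pytest.approx(7.00, abs=0.005)
        assert brain[1] == 3
        assert brain[2] == pytest.approx(0.0060, abs=5e-5)
        body = paired_t([36.9, 37.1, 37.6, 37.5], [36.3, 36.6, 36.8, 37.1])
        assert body[2] == pytest.approx(0.0067, abs=5e-5)

    def test_agrees_with_scipy_on_1000_random_samples(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            b = rng.normal(37.0, 1.0, size=n)
            a = b - rng.normal(0.5, 0.3, size=n)
            if np.std(b - a, ddof=1) == 0.0:
                continue
            t, df, p = paired_t(b, a)
            ref = sps.ttest_rel(b, a)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert df == ref.df

    def test_zero_variance_differences_flagged_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            paired_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestShapiroWilk:
    @pytest.mark.parametrize("sample,W,p", R_SHAPIRO_ORACLE,
                             ids=["normal-quantiles", "one-outlier", "generic", "table1-brain"])
    def test_matches_r_reference(self, sample, W, p):
        w_hat, p_hat = shapiro_wilk(sample)
        assert w_hat == pytest.approx(W, abs=1e-6)
        assert p_hat == pytest.approx(p, rel=1e-4, abs=1e-9)

    def test_near_normal_sample_scores_high(self):
        w, _ = shapiro_wilk(sps.norm.ppf((np.arange(1, 11) - 0.5) / 10))
        assert w > 0.98

    def test_gross_nonnormality_detected(self):
        _, p = shapiro_wilk([1.0] * 9 + [100.0])
        assert p < 0.01

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        w1, _ = shapiro_wilk(x)
        w2, _ = shapiro_wilk(4.2 * x + 11.0)
        assert w1 == pytest.approx(w2, abs=1e-12)

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestSummarizeCohort:
    def test_published_group_statistics(self):
        report = summarize_cohort(table1_records())
        assert report.baseline_brain_mean_C == pytest.approx(36.525, abs=1e-9)
        assert report.baseline_brain_sd_C == pytest.approx(0.3775, abs=1e-3)
        assert report.baseline_body_mean_C == pytest.approx(37.275, abs=1e-9)
        assert report.baseline_body_sd_C == pytest.approx(0.3304, abs=1e-3)
        assert report.rate_body_mean_C_per_h == pytest.approx(0.575, abs=1e-9)
        assert report.rate_body_sd_C_per_h == pytest.approx(0.1708, abs=1e-3)
        assert report.rate_brain_mean_C_per_h == pytest.approx(0.525, abs=1e-9)
        # one-decimal presentation matches the published summaries
        assert round(report.baseline_brain_mean_C, 1) == 36.5
        assert round(report.baseline_brain_sd_C, 1) == 0.4
        assert round(report.baseline_body_mean_C, 1) == 37.3
        assert round(report.baseline_body_sd_C, 1) == 0.3
        assert round(report.rate_body_mean_C_per_h, 1) == 0.6
        assert round(report.rate_body_sd_C_per_h, 1) == 0.2

    def test_published_p_values(self):
        report = summarize_cohort(table1_records())
        assert report.paired["brain"][2] == pytest.approx(0.0060, abs=5e-5)
        assert report.paired["body"][2] == pytest.approx(0.0067, abs=5e-5)
        assert report.paired["brain"][1] == 3

    def test_identical_records_have_zero_sd(self):
        recs = table1_records()[:1] * 2
        report = summarize_cohort(recs)
        assert report.baseline_brain_sd_C == 0.0
        assert np.isnan(report.paired["brain"][2])

    def test_unequal_lengths_raise(self):
        recs = table1_records()
        recs[0].brain_C = recs[0].brain_C[:-5]
        recs[0].body_C = recs[0].body_C[:-5]
        recs[0].time_s = recs[0].time_s[:-5]
        with pytest.raises(ValueError):
            summarize_cohort(recs)

    def test_report_table_renders(self):
        text = summarize_cohort(table1_records()).table()
        assert "paired t" in text and "36.5" in text


class TestCompareSimToExperiment:
    def make_trace_from_mean(self, records, offset=0.0):
        t = records[0].time_s
        brain = np.mean([r.brain_C for r in records], axis=0) + offset
        body = np.mean([r.body_C for r in records], axis=0) + offset
        frame = pd.DataFrame({"time_s": t, "head": brain, "body": body})
        return TemperatureTrace(frame=frame, phase_marks={"cooling_on": 0.0})

    def test_simulation_equal_to_cohort_mean_is_fully_inside(self):
        records = generate_cohort(CohortSpec(seed=11))
        trace = self.make_trace_from_mean(records)
        rep = compare_sim_to_experiment(trace, records)
        assert rep["fraction_inside"]["brain"] == 1.0
        assert rep["fraction_inside"]["body"] == 1.0

    def test_offset_simulation_is_fully_outside(self):
        records = generate_cohort(CohortSpec(seed=11))
        trace = self.make_trace_from_mean(records, offset=10.0)
        rep = compare_sim_to_experiment(trace, records)
        assert rep["fraction_inside"]["brain"] == 0.0
        assert rep["fraction_inside"]["body"] == 0.0

    def test_calibrated_sheep_simulation_inside_cohort_ci(self, sheep_net, sheep_collar):
        """The simulated sheep trajectories sit inside the experimental 95 % CI."""
        trace = run_protocol(sheep_net, sheep_collar,
                             SimulationProtocol(settling_duration_s=0.0))
        records = table1_records()
        rep = compare_sim_to_experiment(trace, records)
        assert rep["fraction_inside"]["brain"] >= 0.9
        assert rep["fraction_inside"]["body"] >= 0.9
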