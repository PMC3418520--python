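"""Average-vs-next contrast and its statistics."""

import numpy as np
import pytest
from scipy import stats

from reachadapt.contrast import (
    BENCHMARK_AVG,
    BENCHMARK_NEXT,
    cohort_contrast,
    contrast_differences,
    extract_condition_clamp_forces,
    extract_post_sequence_forces,
    run_cohort,
    series_repetition_anova,
    two_sample_t,
)
from reachadapt.learners import LearnerParams, run_subject
from reachadapt.schedule import ProtocolConfig, build_schedule


class TestExtraction:
    def test_ten_post_sequence_forces(self, noiseless_averager):
        post = extract_post_sequence_forces(noiseless_averager)
        assert len(post) == 10

    def test_three_sequences_three_values(self):
        sched = build_schedule(ProtocolConfig(n_sequences=3), seed=0)
        sess = run_subject(sched, params=LearnerParams(noise_sd=0.0))
        assert len(extract_post_sequence_forces(sess)) == 3

    def test_no_sequences_raises(self):
        sched = build_schedule(
            ProtocolConfig(n_sequences=0, clamp_fraction_random=0.1), seed=0
        )
        sess = run_subject(sched, params=LearnerParams(noise_sd=0.0))
        with pytest.raises(ValueError):
            extract_post_sequence_forces(sess)

    def test_noiseless_averager_equals_sequence_mean(
        self, noiseless_averager
    ):
        post = extract_post_sequence_forces(noiseless_averager)
        vpk = noiseless_averager.records[0].vy.max()
        assert np.allclose(post, 2.5 * vpk, rtol=0.05)
        assert np.std(post) < 1e-12  # identical by construction

    def test_benchmark_counts(self, noiseless_averager):
        for B in (BENCHMARK_AVG, BENCHMARK_NEXT):
            assert len(
                extract_condition_clamp_forces(noiseless_averager, B)
            ) == 10


class TestTwoSampleT:
    def test_identical_samples(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_textbook_example(self):
        """Two groups with pooled-variance t checked against the
        closed-form computed independently."""
        x = np.array([19.0, 22.0, 24.0, 27.0])
        y = np.array([15.0, 16.0, 18.0, 21.0])
        t, df, p = two_sample_t(x, y)
        # independent closed form
        sp2 = ((3 * x.var(ddof=1)) + (3 * y.var(ddof=1))) / 6
        t_ref = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert df == 6
        assert p == pytest.approx(
            2 * stats.t.sf(abs(t_ref), 6), rel=1e-12
        )

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)
        _, _, p = two_sample_t(x, y)
        assert p < 1e-6

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            two_sample_t([1, 2], [1, 2, 3], paired=True)


class TestContrastDifferences:
    def test_identical_to_benchmark_zero_diff(self):
        post = np.full(10, 1.3)
        res = contrast_differences(post, post, post + 0.7)
        assert res.avg_diff == pytest.approx(0.0)
        assert res.next_diff == pytest.approx(0.7)

    def test_noiseless_averager_cohort(self, noiseless_averager):
        post = extract_post_sequence_forces(noiseless_averager)
        avg = extract_condition_clamp_forces(noiseless_averager, 2.5)
        nxt = extract_condition_clamp_forces(noiseless_averager, 5.0)
        res = contrast_differences(post, avg, nxt)
        vpk = noiseless_averager.records[0].vy.max()
        assert abs(res.avg_diff) < 0.1
        # next_diff approaches (5 - 2.5) * v_peak; benchmark clamps early
        # in a block (before the averaging window converges) pull the
        # 5 Ns/m benchmark somewhat below its asymptote
        assert res.next_diff == pytest.approx(2.5 * vpk, rel=0.2)
        assert abs(res.avg_diff) < abs(res.next_diff)

    def test_noiseless_extrapolator_cohort(self, noiseless_extrapolator):
        post = extract_post_sequence_forces(noiseless_extrapolator)
        avg = extract_condition_clamp_forces(noiseless_extrapolator, 2.5)
        nxt = extract_condition_clamp_forces(noiseless_extrapolator, 5.0)
        res = contrast_differences(post, avg, nxt)
        # block-transition trials make the extrapolator overshoot the
        # 5 Ns/m benchmark slightly; the ordering is what matters
        assert abs(res.next_diff) < 0.35
        assert res.avg_diff < -1.0
        assert abs(res.next_diff) < abs(res.avg_diff)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            contrast_differences([], [1.0], [2.0])


class TestAnova:
    def test_identical_groups_zero_F(self):
        groups = [[2.0, 2.0, 2.0]] * 5
        F, (dfb, dfw), p = series_repetition_anova(groups)
        assert F == pytest.approx(0.0)
        assert (dfb, dfw) == (4, 10)

    def test_injected_trend_detected(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(loc=j, scale=0.5, size=10) for j in range(10)]
        _, _, p = series_repetition_anova(groups)
        assert p < 0.001

    def test_null_pvalues_uniform(self):
        """Under H0 the ANOVA p-value is uniform on (0, 1): KS check
        over 1,000 simulated replicates of 10 groups x 10."""
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(1000):
            groups = rng.normal(size=(10, 10))
            _, _, p = series_repetition_anova(list(groups))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_groups_raises(self):
        with pytest.raises(ValueError):
            series_repetition_anova([[1.0, 2.0]])


class TestCohort:
    def test_cohort_shapes_and_pooling_levels(self, default_schedule):
        sessions = run_cohort(
            default_schedule, "averager", n_subjects=4, seed=0
        )
        obs = cohort_contrast(sessions, level="observation")
        subj = cohort_contrast(sessions, level="subject")
        assert len(obs.lf_post_sequence) == 40
        assert len(subj.lf_post_sequence) == 4
        assert obs.anova_df == (9, 30)
        # pooled means agree across levels
        assert np.mean(obs.lf_post_sequence) == pytest.approx(
            np.mean(subj.lf_post_sequence)
        )

    def test_invalid_level_rejected(self, default_schedule):
        sessions = run_cohort(
            default_schedule, "averager", n_subjects=2, seed=0
        )
        with pytest.raises(ValueError):
            cohort_contrast(sessions, level="trial")

    def test_cohort_deterministic(self, default_schedule):
        a = run_cohort(default_schedule, "averager", n_subjects=2, seed=9)
        b = run_cohort(default_schedule, "averager", n_subjects=2, seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(
                extract_post_sequence_forces(sa),
                extract_post_sequence_forces(sb),
            )
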