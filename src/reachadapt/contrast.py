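"""The headline contrast: average-of-the-past vs next-in-series.

After experiencing an embedded increasing sequence of fields
(1, 2, 3, 4 Ns/m), what does the learner express on the probe clamp
that follows — roughly the sequence mean (2.5 Ns/m, "average"
hypothesis) or the next term (5 Ns/m, "next" hypothesis)?  The
post-sequence clamp forces are compared against the forces expressed
in the constant-phase clamp trials of the 2.5 Ns/m and 5 Ns/m
conditions, which serve as empirical benchmarks for the two
hypotheses:

* ``avg_diff``  = mean(benchmark 2.5) - mean(post-sequence force)
* ``next_diff`` = mean(benchmark 5)   - mean(post-sequence force)

The hypothesis whose benchmark the post-sequence force sits closer to
wins; a two-tailed t-test between the per-observation absolute
difference distributions quantifies the dissociation.  A one-way ANOVA
across the sequence repetitions tests for implicit learning of the
series over the session (a stationary learner should show none).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .analysis import force_at_max_speed
from .kinematics import SimConfig
from .learners import LearnerParams, SessionData, run_subject
from .schedule import Schedule

__all__ = [
    "ContrastResult",
    "extract_post_sequence_forces",
    "extract_condition_clamp_forces",
    "two_sample_t",
    "contrast_differences",
    "series_repetition_anova",
    "run_cohort",
    "cohort_contrast",
]

#: Benchmark conditions, Ns/m: the sequence mean and the next term.
BENCHMARK_AVG = 2.5
BENCHMARK_NEXT = 5.0


@dataclass
class ContrastResult:
    """Differences, test statistics and ANOVA for one contrast.

    ``avg_diff`` / ``next_diff`` are benchmark minus post-sequence mean
    (positive when the benchmark force exceeds the post-sequence
    force).  ``t_stats`` / ``p_values`` hold the post-vs-benchmark
    t-tests plus the comparison between the two absolute-difference
    distributions (key ``"avg_vs_next"``).
    """

    lf_post_sequence: np.ndarray
    lf_benchmark_avg: np.ndarray
    lf_benchmark_next: np.ndarray
    avg_diff: float
    next_diff: float
    t_stats: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    df: dict = field(default_factory=dict)
    anova_F: float = float("nan")
    anova_p: float = float("nan")
    anova_df: tuple = (0, 0)


def extract_post_sequence_forces(session: SessionData) -> np.ndarray:
    """Force at max speed on each sequence-trailing clamp.

    Returned in sequence-repetition order (one value per embedded
    sequence).  Raises if the schedule contains no tagged sequences.
    """
    tagged = [
        (r.spec.sequence_id, r)
        for r in session.records
        if r.spec is not None and r.spec.is_clamp and r.spec.sequence_id is not None
    ]
    if not tagged:
        raise ValueError("schedule contains no sequence-trailing clamp trials")
    tagged.sort(key=lambda pair: pair[0])
    return np.array(
        [force_at_max_speed(r.fx, r.vy) for _, r in tagged]
    )


def extract_condition_clamp_forces(
    session: SessionData, B: float
) -> np.ndarray:
    """Forces at max speed from the constant-phase clamps of condition ``B``."""
    out = []
    for r in session.records:
        spec = r.spec
        if (
            spec is not None
            and spec.is_clamp
            and spec.block_id is not None
            and session.schedule.block_amplitude(spec.block_id) == B
        ):
            out.append(force_at_max_speed(r.fx, r.vy))
    if not out:
        raise ValueError(f"no constant-phase clamps found for B = {B} Ns/m")
    return np.array(out)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> tuple[float, float, float]:
    """Two-tailed t-test; returns ``(t, df, p)``.

    Independent (pooled-variance) by default; ``paired=True`` runs the
    paired test on equal-length samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        res = stats.ttest_rel(x, y)
        df = len(x) - 1
    else:
        res = stats.ttest_ind(x, y)
        df = len(x) + len(y) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def contrast_differences(
    post_seq: Sequence[float],
    bench_avg: Sequence[float],
    bench_next: Sequence[float],
    paired: bool = False,
) -> ContrastResult:
    """Compute the average/next differences and their statistics.

    The decisive test compares the per-observation absolute deviations
    ``|bench_avg_i - post_i|`` vs ``|bench_next_i - post_i|`` (pairing
    by observation index), answering which benchmark the post-sequence
    forces are closer to.
    """
    post = np.asarray(post_seq, dtype=float)
    avg = np.asarray(bench_avg, dtype=float)
    nxt = np.asarray(bench_next, dtype=float)
    if post.size == 0 or avg.size == 0 or nxt.size == 0:
        raise ValueError("all three force lists must be non-empty")

    result = ContrastResult(
        lf_post_sequence=post,
        lf_benchmark_avg=avg,
        lf_benchmark_next=nxt,
        avg_diff=float(avg.mean() - post.mean()),
        next_diff=float(nxt.mean() - post.mean()),
    )
    for key, bench in (("avg", avg), ("next", nxt)):
        t, df, p = two_sample_t(bench, post, paired=False)
        result.t_stats[key] = t
        result.p_values[key] = p
        result.df[key] = df
    if len(post) == len(avg) == len(nxt):
        d_avg = np.abs(avg - post)
        d_next = np.abs(nxt - post)
        t, df, p = two_sample_t(d_avg, d_next, paired=paired)
        result.t_stats["avg_vs_next"] = t
        result.p_values["avg_vs_next"] = p
        result.df["avg_vs_next"] = df
    return result


def series_repetition_anova(
    groups: Sequence[Sequence[float]],
) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA across sequence repetitions.

    ``groups[i]`` holds the post-sequence forces of repetition ``i``
    across subjects.  Returns ``(F, (df_between, df_within), p)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    if np.var(np.concatenate(groups)) == 0:
        # no variance anywhere: no effect by definition (0/0 otherwise)
        return 0.0, (df_between, df_within), 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), (df_between, df_within), float(p)


def run_cohort(
    schedule: Schedule,
    learner: str,
    params: Optional[LearnerParams] = None,
    sim_config: Optional[SimConfig] = None,
    n_subjects: int = 10,
    seed: int = 0,
) -> list[SessionData]:
    """Simulate ``n_subjects`` subjects of one learner on one schedule.

    All subjects share the schedule (as in the protocol: same block
    order for everyone); per-subject randomness (motor noise) comes
    from seeds derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_subjects) % (2**31)
    return [
        run_subject(
            schedule,
            learner=learner,
            params=params,
            sim_config=sim_config,
            seed=int(s),
        )
        for s in child_seeds
    ]


def cohort_contrast(
    sessions: Sequence[SessionData],
    level: str = "observation",
    paired: bool = False,
) -> ContrastResult:
    """Pool a cohort and run the full contrast.

    ``level="observation"`` pools every clamp observation across
    subjects (10 subjects x 10 clamps -> n = 100 per group, matching
    the t(99)-style degrees of freedom of observation-level pooling);
    ``level="subject"`` first averages within subject (n = subjects).
    The repetition ANOVA uses one group per sequence repetition with
    one observation per subject.
    """
    if level not in ("observation", "subject"):
        raise ValueError("level must be 'observation' or 'subject'")
    post_rows = [extract_post_sequence_forces(s) for s in sessions]
    avg_rows = [
        extract_condition_clamp_forces(s, BENCHMARK_AVG) for s in sessions
    ]
    next_rows = [
        extract_condition_clamp_forces(s, BENCHMARK_NEXT) for s in sessions
    ]
    if level == "observation":
        post = np.concatenate(post_rows)
        avg = np.concatenate(avg_rows)
        nxt = np.concatenate(next_rows)
    else:
        post = np.array([r.mean() for r in post_rows])
        avg = np.array([r.mean() for r in avg_rows])
        nxt = np.array([r.mean() for r in next_rows])
    result = contrast_differences(post, avg, nxt, paired=paired)

    post_mat = np.vstack(post_rows)  # subjects x repetitions
    if post_mat.shape[0] >= 2:
        groups = [post_mat[:, j] for j in range(post_mat.shape[1])]
        F, dfs, p = series_repetition_anova(groups)
        result.anova_F, result.anova_df, result.anova_p = F, dfs, p
    return result
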