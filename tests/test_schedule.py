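"""Protocol schedule: counts, embedding, validation, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from reachadapt.schedule import (
    Phase,
    ProtocolConfig,
    Schedule,
    ScheduleError,
    TrialSpec,
    TrialType,
    build_schedule,
    embed_sequences,
    load_protocol_config,
    validate_schedule,
)


class TestBuildSchedule:
    def test_default_phase_counts(self, default_schedule):
        counts = {
            p: len(default_schedule.phase_trials(p)) for p in Phase
        }
        assert len(default_schedule) == 780
        assert counts[Phase.baseline] == 100
        assert counts[Phase.random] == 200
        assert counts[Phase.constant] == 480

    def test_baseline_is_null_field(self, default_schedule):
        for t in default_schedule.phase_trials(Phase.baseline):
            assert t.trial_type is TrialType.null_field
            assert t.B == 0.0

    def test_random_phase_clamp_structure(self, default_schedule):
        clamps = [
            t
            for t in default_schedule.phase_trials(Phase.random)
            if t.is_clamp
        ]
        assert len(clamps) == 20  # 10% of 200
        trailing = [t for t in clamps if t.sequence_id is not None]
        assert len(trailing) == 10  # one per embedded sequence
        # each trailing clamp immediately follows its 4 sequence trials
        for c in trailing:
            body = [
                t
                for t in default_schedule
                if t.sequence_id == c.sequence_id and not t.is_clamp
            ]
            assert [t.B for t in body] == [1.0, 2.0, 3.0, 4.0]
            assert [t.index for t in body] + [c.index] == list(
                range(body[0].index, body[0].index + 5)
            )

    def test_constant_phase_blocks(self, default_schedule):
        const = default_schedule.phase_trials(Phase.constant)
        blocks = {}
        for t in const:
            blocks.setdefault(t.block_id, []).append(t)
        assert len(blocks) == 12
        amps = []
        for bid, ts in blocks.items():
            assert len(ts) == 40
            clamps = [
                i for i, t in enumerate(sorted(ts, key=lambda t: t.index))
                if t.is_clamp
            ]
            assert len(clamps) == 5  # 12.5% of 40
            assert 0 not in clamps
            amps.append(default_schedule.block_amplitude(bid))
        assert sorted(amps) == sorted([1, 2, 2.5, 3, 4, 5] * 2)

    def test_degenerate_config_no_sequences_no_clamps(self):
        cfg = ProtocolConfig(n_sequences=0, clamp_fraction_random=0.0)
        sched = build_schedule(cfg, seed=0)
        random_trials = sched.phase_trials(Phase.random)
        assert len(random_trials) == 200
        assert all(
            t.trial_type is TrialType.force_field for t in random_trials
        )

    def test_background_amplitudes_in_allowed_set(self, default_schedule):
        allowed = {1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0}
        for t in default_schedule.phase_trials(Phase.random):
            if t.trial_type is TrialType.force_field and t.sequence_id is None:
                assert t.B in allowed

    def test_determinism_byte_identical(self, tmp_path):
        paths = []
        for run in range(2):
            p = tmp_path / f"s{run}.csv"
            build_schedule(seed=42).to_csv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
        other = tmp_path / "other.csv"
        build_schedule(seed=43).to_csv(other)
        assert other.read_bytes() != paths[0]

    def test_block_order_override(self):
        order = [1.0, 1.0, 2.0, 2.0, 2.5, 2.5, 3.0, 3.0, 4.0, 4.0, 5.0, 5.0]
        sched = build_schedule(ProtocolConfig(block_order=order), seed=0)
        got = [sched.block_amplitude(b) for b in range(12)]
        assert got == order

    def test_infeasible_clamp_fraction_raises(self):
        with pytest.raises(ScheduleError):
            build_schedule(
                ProtocolConfig(clamp_fraction_random=0.01), seed=0
            )
        with pytest.raises(ScheduleError):
            ProtocolConfig(clamp_fraction_random=1.5).validate()

    def test_csv_round_trip(self, default_schedule, tmp_path):
        p = tmp_path / "sched.csv"
        default_schedule.to_csv(p)
        back = Schedule.from_csv(p)
        assert len(back) == len(default_schedule)
        for a, b in zip(back, default_schedule):
            assert a.trial_type is b.trial_type
            assert a.sequence_id == b.sequence_id
            assert a.block_id == b.block_id
            assert (a.B == b.B) or (np.isnan(a.B) and np.isnan(b.B))


class TestEmbedSequences:
    def test_default_ten_placements_disjoint(self):
        starts = embed_sequences(200, 10, [1, 2, 3, 4], seed=0)
        assert len(starts) == 10
        spans = [set(range(s, s + 5)) for s in starts]
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                assert not (spans[i] & spans[j])
        # at least one non-sequence trial between consecutive blocks
        for a, b in zip(starts, starts[1:]):
            assert b - a >= 6
        assert starts[-1] + 5 <= 200

    def test_zero_sequences_empty(self):
        assert embed_sequences(200, 0, [1, 2, 3, 4], seed=0) == []

    def test_infeasible_raises(self):
        # 40 length-5 blocks need 200 slots plus >= 39 gaps
        with pytest.raises(ScheduleError):
            embed_sequences(200, 40, [1, 2, 3, 4], seed=0)

    def test_deterministic_given_seed(self):
        a = embed_sequences(200, 10, [1, 2, 3, 4], seed=5)
        b = embed_sequences(200, 10, [1, 2, 3, 4], seed=5)
        assert a == b


class TestValidateSchedule:
    def test_valid_schedule_empty_report(self, default_schedule):
        assert validate_schedule(default_schedule) == []

    def test_flags_baseline_with_field(self, default_schedule):
        trials = list(default_schedule.trials)
        trials[0] = dataclasses.replace(
            trials[0], trial_type=TrialType.force_field, B=2.0
        )
        bad = Schedule(trials, default_schedule.config, 1)
        report = validate_schedule(bad)
        assert any("baseline" in msg for msg in report)

    def test_flags_short_block(self, default_schedule):
        drop = min(
            t.index for t in default_schedule.trials if t.block_id == 3
        )
        trials = [t for t in default_schedule.trials if t.index != drop]
        bad = Schedule(trials, default_schedule.config, 1)
        report = validate_schedule(bad)
        assert any("block 3" in msg for msg in report)

    def test_flags_broken_sequence(self, default_schedule):
        trials = list(default_schedule.trials)
        i = next(
            k
            for k, t in enumerate(trials)
            if t.sequence_id == 0 and not t.is_clamp
        )
        trials[i] = dataclasses.replace(trials[i], B=9.0)
        report = validate_schedule(
            Schedule(trials, default_schedule.config, 1)
        )
        assert any("sequence 0" in msg for msg in report)


def test_background_amplitude_uniformity():
    """Across seeds, non-sequence field amplitudes are uniform over the
    7-value set (chi-square goodness of fit at >= 10,000 draws)."""
    draws = []
    seed = 0
    while len(draws) < 10_000:
        sched = build_schedule(seed=seed)
        draws.extend(
            t.B
            for t in sched.phase_trials(Phase.random)
            if t.trial_type is TrialType.force_field and t.sequence_id is None
        )
        seed += 1
    _, counts = np.unique(np.array(draws), return_counts=True)
    assert len(counts) == 7
    assert stats.chisquare(counts).pvalue > 0.01


def test_config_yaml_round_trip(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("n_sequences: 5\nclamp_fraction_random: 0.1\n")
    cfg = load_protocol_config(p)
    assert cfg.n_sequences == 5
    sched = build_schedule(cfg, seed=0)
    assert validate_schedule(sched) == []
    p.write_text("bogus_key: 1\n")
    with pytest.raises(ScheduleError):
        load_protocol_config(p)
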