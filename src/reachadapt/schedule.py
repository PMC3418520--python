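"""Three-phase experimental protocol: schedule generation and validation.

A session is an ordered list of trials split into three phases:

* **baseline** — null-field trials (no perturbation),
* **random** — viscous curl fields whose amplitude ``B`` varies
  pseudo-randomly from trial to trial, with short increasing sequences
  (1, 2, 3, 4 Ns/m) embedded at random positions, each followed by an
  error-clamp trial that probes the learner's expectation,
* **constant** — blocks of a fixed field amplitude with error-clamp
  trials interspersed, providing per-condition adaptation benchmarks.

Defaults reproduce the 780-trial protocol: 100 baseline, 200 random
(10 embedded sequences, 10% clamps), and 480 constant trials arranged
as 12 blocks of 40 (six amplitudes, two blocks each, 5 clamps per
block, i.e. 12.5%).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Phase",
    "TrialType",
    "TrialSpec",
    "ProtocolConfig",
    "Schedule",
    "ScheduleError",
    "build_schedule",
    "embed_sequences",
    "validate_schedule",
    "load_protocol_config",
]

#: Amplitudes the random-phase background is drawn from, in Ns/m.
RANDOM_PHASE_AMPLITUDES = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

#: Constant-phase conditions, in Ns/m; each occupies two 40-trial blocks.
CONSTANT_CONDITIONS = (1.0, 2.0, 2.5, 3.0, 4.0, 5.0)

#: The embedded increasing sequence, in Ns/m.
SEQUENCE_AMPLITUDES = (1.0, 2.0, 3.0, 4.0)


class Phase(str, Enum):
    baseline = "baseline"
    random = "random"
    constant = "constant"


class TrialType(str, Enum):
    null_field = "null_field"
    force_field = "force_field"
    error_clamp = "error_clamp"


class ScheduleError(ValueError):
    """Raised for infeasible or invalid protocol configurations."""


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the protocol.

    ``B`` is the viscous field amplitude in Ns/m; it is 0 for null-field
    trials and NaN for error-clamp trials (no field is applied there; the
    channel measures the expressed force instead).  ``sequence_id`` tags
    the four trials of an embedded increasing sequence and the clamp that
    immediately follows it; ``block_id`` tags constant-phase blocks.
    Trial indices are 0-based throughout, including serialized files.
    """

    index: int
    phase: Phase
    trial_type: TrialType
    B: float
    sequence_id: Optional[int] = None
    block_id: Optional[int] = None

    @property
    def is_clamp(self) -> bool:
        return self.trial_type is TrialType.error_clamp


@dataclass
class ProtocolConfig:
    """Parameters of the three-phase schedule; defaults give 780 trials."""

    n_baseline: int = 100
    n_random: int = 200
    block_length: int = 40
    blocks_per_condition: int = 2
    condition_amplitudes: Sequence[float] = CONSTANT_CONDITIONS
    sequence_amplitudes: Sequence[float] = SEQUENCE_AMPLITUDES
    n_sequences: int = 10
    random_amplitudes: Sequence[float] = RANDOM_PHASE_AMPLITUDES
    clamp_fraction_random: float = 0.10
    clamp_fraction_constant: float = 0.125
    #: Explicit block amplitude order for the constant phase; ``None``
    #: draws a seed-determined permutation shared by all subjects.
    block_order: Optional[Sequence[float]] = None

    @property
    def n_constant(self) -> int:
        return self.block_length * self.blocks_per_condition * len(
            self.condition_amplitudes
        )

    @property
    def n_blocks(self) -> int:
        return self.blocks_per_condition * len(self.condition_amplitudes)

    @property
    def n_total(self) -> int:
        return self.n_baseline + self.n_random + self.n_constant

    def validate(self) -> None:
        if min(self.n_baseline, self.n_random, self.block_length) <= 0:
            raise ScheduleError("phase lengths and block length must be positive")
        for name in ("clamp_fraction_random", "clamp_fraction_constant"):
            f = getattr(self, name)
            if not 0.0 <= f < 1.0:
                raise ScheduleError(f"{name} must lie in [0, 1), got {f}")
        if self.n_sequences < 0:
            raise ScheduleError("n_sequences must be non-negative")
        if self.n_sequences * (len(self.sequence_amplitudes) + 1) > self.n_random:
            raise ScheduleError(
                "embedded sequences do not fit in the random phase"
            )
        n_seq_clamps = self.n_sequences
        if self.random_clamp_count < n_seq_clamps:
            raise ScheduleError(
                "clamp_fraction_random yields fewer clamps than embedded "
                "sequences require"
            )
        if self.block_order is not None:
            want = sorted(
                list(self.condition_amplitudes) * self.blocks_per_condition
            )
            if sorted(self.block_order) != want:
                raise ScheduleError(
                    "block_order must contain each condition amplitude exactly "
                    f"{self.blocks_per_condition} times"
                )

    @property
    def random_clamp_count(self) -> int:
        return int(round(self.clamp_fraction_random * self.n_random))

    @property
    def clamps_per_block(self) -> int:
        return int(round(self.clamp_fraction_constant * self.block_length))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("condition_amplitudes", "sequence_amplitudes",
                    "random_amplitudes", "block_order"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def load_protocol_config(path: str) -> ProtocolConfig:
    """Read a :class:`ProtocolConfig` from a YAML or JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    known = {f.name for f in dataclasses.fields(ProtocolConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ScheduleError(f"unknown config keys: {sorted(unknown)}")
    cfg = ProtocolConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class Schedule:
    """An ordered trial list plus the parameters that generated it."""

    trials: list[TrialSpec]
    config: Optional[ProtocolConfig]
    seed: Optional[int]

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def phase_trials(self, phase: Phase) -> list[TrialSpec]:
        return [t for t in self.trials if t.phase is phase]

    def block_amplitude(self, block_id: int) -> float:
        """Field amplitude of a constant-phase block (from its force trials)."""
        for t in self.trials:
            if t.block_id == block_id and t.trial_type is TrialType.force_field:
                return t.B
        raise KeyError(f"no force trials found for block {block_id}")

    def sequence_amplitudes_of(self, sequence_id: int) -> list[float]:
        """Amplitudes of one embedded sequence, in trial order."""
        amps = [
            t.B
            for t in self.trials
            if t.sequence_id == sequence_id
            and t.trial_type is TrialType.force_field
        ]
        if not amps:
            raise KeyError(f"no sequence with id {sequence_id}")
        return amps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "phase": [t.phase.value for t in self.trials],
                "trial_type": [t.trial_type.value for t in self.trials],
                "B": [t.B for t in self.trials],
                "sequence_id": [t.sequence_id for t in self.trials],
                "block_id": [t.block_id for t in self.trials],
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "Schedule":
        df = pd.read_csv(path)
        trials = []
        for _, row in df.iterrows():
            trials.append(
                TrialSpec(
                    index=int(row["index"]),
                    phase=Phase(row["phase"]),
                    trial_type=TrialType(row["trial_type"]),
                    B=float(row["B"]) if not pd.isna(row["B"]) else math.nan,
                    sequence_id=None
                    if pd.isna(row["sequence_id"])
                    else int(row["sequence_id"]),
                    block_id=None
                    if pd.isna(row["block_id"])
                    else int(row["block_id"]),
                )
            )
        return cls(trials=trials, config=None, seed=None)


def embed_sequences(
    n_slots: int,
    n_sequences: int,
    amplitudes: Sequence[float],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[int]:
    """Place non-overlapping sequence blocks into a run of trial slots.

    Each placement reserves ``len(amplitudes)`` consecutive force trials
    plus one trailing error-clamp trial; consecutive placements are
    separated by at least one non-sequence trial.  Returns the sorted
    start positions.  Deterministic given the seed (or generator).
    """
    if n_sequences == 0:
        return []
    if rng is None:
        rng = np.random.default_rng(seed)
    block_len = len(amplitudes) + 1
    # With a mandatory 1-slot gap between blocks the n blocks consume
    # n*block_len + (n-1) slots; the leftover slack is distributed freely.
    slack = n_slots - n_sequences * block_len - (n_sequences - 1)
    if slack < 0:
        raise ScheduleError(
            f"cannot place {n_sequences} sequence blocks of length "
            f"{block_len} (plus gaps) in {n_slots} slots"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n_sequences))
    starts = offsets + np.arange(n_sequences) * (block_len + 1)
    return [int(s) for s in starts]


def build_schedule(
    config: Optional[ProtocolConfig] = None, seed: int = 0
) -> Schedule:
    """Generate the full three-phase schedule.

    Deterministic given ``(config, seed)``.  Raises :class:`ScheduleError`
    for infeasible configurations (sequences that cannot be embedded,
    clamp fractions inconsistent with the sequence count, ...).
    """
    if config is None:
        config = ProtocolConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    idx = 0

    for _ in range(config.n_baseline):
        trials.append(TrialSpec(idx, Phase.baseline, TrialType.null_field, 0.0))
        idx += 1

    trials.extend(_build_random_phase(config, rng, idx))
    idx += config.n_random

    trials.extend(_build_constant_phase(config, rng, idx))

    return Schedule(trials=trials, config=config, seed=seed)


def _build_random_phase(
    config: ProtocolConfig, rng: np.random.Generator, start_index: int
) -> list[TrialSpec]:
    R = config.n_random
    seq_amps = list(config.sequence_amplitudes)
    seq_len = len(seq_amps) + 1
    starts = embed_sequences(R, config.n_sequences, seq_amps, rng=rng)

    trial_type: list[TrialType] = [TrialType.force_field] * R
    amp = np.full(R, np.nan)
    seq_id: list[Optional[int]] = [None] * R
    for i, s in enumerate(starts):
        for j, a in enumerate(seq_amps):
            trial_type[s + j] = TrialType.force_field
            amp[s + j] = a
            seq_id[s + j] = i
        trial_type[s + seq_len - 1] = TrialType.error_clamp
        seq_id[s + seq_len - 1] = i

    # Extra clamps (beyond the sequence-trailing ones) go to uniformly
    # random background positions, never adjacent to a sequence block.
    n_extra = config.random_clamp_count - config.n_sequences
    blocked: set[int] = set()
    for s in starts:
        blocked.update(range(s - 1, s + seq_len + 1))
    candidates = np.array(
        [p for p in range(R) if seq_id[p] is None and p not in blocked],
        dtype=int,
    )
    if n_extra > len(candidates):
        raise ScheduleError(
            "not enough background positions for the extra error-clamp trials"
        )
    if n_extra > 0:
        extra = rng.choice(candidates, size=n_extra, replace=False)
        for p in extra:
            trial_type[p] = TrialType.error_clamp
            amp[p] = np.nan

    out = []
    for p in range(R):
        tt = trial_type[p]
        if tt is TrialType.force_field and seq_id[p] is None:
            # background field amplitude: uniform over the configured set
            amp[p] = rng.choice(config.random_amplitudes)
        out.append(
            TrialSpec(
                index=start_index + p,
                phase=Phase.random,
                trial_type=tt,
                B=float(amp[p]) if tt is TrialType.force_field else math.nan,
                sequence_id=seq_id[p],
            )
        )
    return out


def _build_constant_phase(
    config: ProtocolConfig, rng: np.random.Generator, start_index: int
) -> list[TrialSpec]:
    if config.block_order is not None:
        order = list(config.block_order)
    else:
        conditions = np.repeat(
            np.asarray(config.condition_amplitudes, dtype=float),
            config.blocks_per_condition,
        )
        order = [float(b) for b in rng.permutation(conditions)]

    out = []
    idx = start_index
    for block_id, B in enumerate(order):
        cpb = config.clamps_per_block
        # clamps never occupy the first trial of a block: the first trial
        # of a new condition must expose the learner to the new field
        clamp_offsets = set(
            int(o)
            for o in rng.choice(
                np.arange(1, config.block_length), size=cpb, replace=False
            )
        )
        for offset in range(config.block_length):
            is_clamp = offset in clamp_offsets
            out.append(
                TrialSpec(
                    index=idx,
                    phase=Phase.constant,
                    trial_type=TrialType.error_clamp
                    if is_clamp
                    else TrialType.force_field,
                    B=math.nan if is_clamp else float(B),
                    block_id=block_id,
                )
            )
            idx += 1
    return out


def validate_schedule(schedule: Schedule) -> list[str]:
    """Check a schedule against the protocol invariants.

    Returns a list of human-readable violation messages; an empty list
    means the schedule is valid.  Never raises on content.
    """
    report: list[str] = []
    config = schedule.config or ProtocolConfig()

    by_phase = {p: schedule.phase_trials(p) for p in Phase}
    counts = {p: len(ts) for p, ts in by_phase.items()}
    expected = {
        Phase.baseline: config.n_baseline,
        Phase.random: config.n_random,
        Phase.constant: config.n_constant,
    }
    for p, want in expected.items():
        if counts[p] != want:
            report.append(
                f"{p.value} phase has {counts[p]} trials, expected {want}"
            )

    for t in by_phase[Phase.baseline]:
        if t.trial_type is not TrialType.null_field or t.B != 0.0:
            report.append(
                f"trial {t.index}: baseline must be null_field with B = 0"
            )

    amp_set = set(config.random_amplitudes)
    n_clamps = 0
    for t in by_phase[Phase.random]:
        if t.trial_type is TrialType.error_clamp:
            n_clamps += 1
        elif t.trial_type is TrialType.force_field and t.sequence_id is None:
            if t.B not in amp_set:
                report.append(
                    f"trial {t.index}: background amplitude {t.B} outside "
                    f"the configured set"
                )
    if n_clamps != config.random_clamp_count:
        report.append(
            f"random phase has {n_clamps} error-clamp trials, expected "
            f"{config.random_clamp_count}"
        )

    report.extend(_check_sequences(schedule, config))
    report.extend(_check_blocks(by_phase[Phase.constant], config))
    return report


def _check_sequences(schedule: Schedule, config: ProtocolConfig) -> list[str]:
    report = []
    groups: dict[int, list[TrialSpec]] = {}
    for t in schedule.trials:
        if t.sequence_id is not None:
            groups.setdefault(t.sequence_id, []).append(t)
    if len(groups) != config.n_sequences:
        report.append(
            f"found {len(groups)} tagged sequences, expected {config.n_sequences}"
        )
    want = [float(a) for a in config.sequence_amplitudes]
    for sid, ts in groups.items():
        ts = sorted(ts, key=lambda t: t.index)
        idxs = [t.index for t in ts]
        if idxs != list(range(idxs[0], idxs[0] + len(idxs))):
            report.append(f"sequence {sid} trials are not consecutive")
        if len(ts) != len(want) + 1:
            report.append(
                f"sequence {sid} has {len(ts)} trials, expected {len(want) + 1}"
            )
            continue
        body, clamp = ts[:-1], ts[-1]
        if [t.B for t in body] != want or any(
            t.trial_type is not TrialType.force_field for t in body
        ):
            report.append(
                f"sequence {sid} amplitudes are not {want} in order"
            )
        if clamp.trial_type is not TrialType.error_clamp:
            report.append(f"sequence {sid} is not followed by an error clamp")
    return report


def _check_blocks(
    constant_trials: list[TrialSpec], config: ProtocolConfig
) -> list[str]:
    report = []
    blocks: dict[int, list[TrialSpec]] = {}
    for t in constant_trials:
        if t.block_id is None:
            report.append(f"trial {t.index}: constant-phase trial lacks block_id")
            continue
        blocks.setdefault(t.block_id, []).append(t)
    amp_count: dict[float, int] = {}
    for bid, ts in sorted(blocks.items()):
        ts = sorted(ts, key=lambda t: t.index)
        if len(ts) != config.block_length:
            report.append(
                f"block {bid} has {len(ts)} trials, expected {config.block_length}"
            )
        amps = {t.B for t in ts if t.trial_type is TrialType.force_field}
        if len(amps) != 1:
            report.append(f"block {bid} mixes field amplitudes {sorted(amps)}")
        else:
            (B,) = amps
            amp_count[B] = amp_count.get(B, 0) + 1
        clamps = [i for i, t in enumerate(ts) if t.is_clamp]
        if len(clamps) != config.clamps_per_block:
            report.append(
                f"block {bid} has {len(clamps)} clamps, expected "
                f"{config.clamps_per_block}"
            )
        if clamps and clamps[0] == 0:
            report.append(f"block {bid} starts with an error clamp")
    for B in config.condition_amplitudes:
        got = amp_count.get(float(B), 0)
        if got != config.blocks_per_condition:
            report.append(
                f"condition {B} Ns/m appears in {got} blocks, expected "
                f"{config.blocks_per_condition}"
            )
    return report
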