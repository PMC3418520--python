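"""Synthetic subjects: trial-by-trial learners run over a schedule.

Two hypotheses about how the motor system predicts the next
perturbation are shipped as learners:

* **averager** — the feedforward gain tracks a weighted mean of
  recently experienced field amplitudes.  Two update laws are
  available: a sliding-window (FIR) mean over the last ``k`` trials,
  and a single-rate state-space update
  ``B_hat <- A * B_hat + eta * (B_exp - B_hat)``.
* **extrapolator** — the gain is the one-step linear extrapolation of
  the recent amplitudes: an ordinary-least-squares line through the
  last ``k`` (trial, amplitude) pairs evaluated at the next trial.
  After an increasing sequence 1, 2, 3, 4 Ns/m it predicts 5 Ns/m,
  whereas the window averager predicts the sequence mean 2.5 Ns/m.

Both laws are hypothesis instantiations, not claims about subjects.
Error-clamp trials present (almost) no error signal and by default
leave the learner state untouched; an optional retention multiplier
can decay the gain instead.  Null-field trials count as experiencing
an amplitude of zero.
"""

from __future__ import annotations

import json
import os
from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import kinematics
from .kinematics import SimConfig, TrialRecord, minjerk_profile
from .schedule import Schedule, TrialType

__all__ = [
    "LearnerParams",
    "LearnerState",
    "SessionData",
    "averager_update",
    "extrapolator_predict",
    "make_learner",
    "run_subject",
    "LEARNERS",
]


@dataclass
class LearnerParams:
    """Parameters shared by the shipped learners.

    ``k`` — history window (trials); ``eta`` — single-rate learning
    rate; ``retention`` — multiplier applied to the gain on error-clamp
    trials (1 = frozen state, the default); ``noise_sd`` — motor noise,
    the standard deviation of a zero-mean Gaussian scaling of the
    expressed gain, as a fraction of ``B_hat`` (default 5%);
    ``baseline_seeding`` — pre-fill the history window with zeros so the
    zero-field baseline participates in the average;
    ``law`` — ``"fir"`` or ``"single_rate"`` for the averager.
    """

    k: int = 4
    eta: float = 0.3
    retention: float = 1.0
    noise_sd: float = 0.05
    baseline_seeding: bool = True
    law: str = "fir"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("window k must be >= 1")
        if self.law not in ("fir", "single_rate"):
            raise ValueError("law must be 'fir' or 'single_rate'")


@dataclass
class LearnerState:
    """A learner's internal gain estimate and its recent history."""

    B_hat: float
    history: deque
    params: LearnerParams

    @classmethod
    def initial(cls, params: LearnerParams) -> "LearnerState":
        hist: deque = deque(maxlen=params.k)
        if params.baseline_seeding:
            hist.extend([0.0] * params.k)
        return cls(B_hat=0.0, history=hist, params=params)


def averager_update(
    state: LearnerState, experienced_B: float, trial_type: TrialType
) -> LearnerState:
    """Advance an averaging learner by one trial.

    On error-clamp trials there is no experienced amplitude: the state
    is frozen apart from the optional retention decay.  Otherwise the
    configured law (FIR window mean or single-rate) is applied with the
    experienced amplitude (0 on null-field trials).
    """
    p = state.params
    if trial_type is TrialType.error_clamp:
        return LearnerState(
            B_hat=p.retention * state.B_hat,
            history=state.history.copy(),
            params=p,
        )
    hist = state.history.copy()
    hist.append(float(experienced_B))
    if p.law == "fir":
        B_hat = float(np.mean(hist))
    else:
        B_hat = state.B_hat + p.eta * (float(experienced_B) - state.B_hat)
    return LearnerState(B_hat=B_hat, history=hist, params=p)


def extrapolator_predict(history: Sequence[float]) -> float:
    """One-step-ahead linear extrapolation of recent amplitudes.

    Fits an ordinary-least-squares line to ``(i, history[i])`` and
    evaluates it at the next index, predicting the next term of a
    linear series: ``[1, 2, 3, 4] -> 5``.
    """
    h = np.asarray(history, dtype=float)
    if len(h) < 2:
        raise ValueError("extrapolation needs at least 2 history values")
    x = np.arange(len(h), dtype=float)
    slope, intercept = np.polyfit(x, h, 1)
    return float(slope * len(h) + intercept)


class _Averager:
    """Averaging learner (FIR window or single-rate law)."""

    def __init__(self, params: LearnerParams):
        self.state = LearnerState.initial(params)

    def predict(self) -> float:
        return self.state.B_hat

    def update(self, experienced_B: float, trial_type: TrialType) -> None:
        self.state = averager_update(self.state, experienced_B, trial_type)


class _Extrapolator:
    """Trend-extrapolating learner over a sliding window of amplitudes."""

    def __init__(self, params: LearnerParams):
        self.state = LearnerState.initial(params)

    def predict(self) -> float:
        if len(self.state.history) >= 2:
            return extrapolator_predict(list(self.state.history))
        return self.state.B_hat

    def update(self, experienced_B: float, trial_type: TrialType) -> None:
        p = self.state.params
        if trial_type is TrialType.error_clamp:
            self.state.B_hat *= p.retention
            return
        self.state.history.append(float(experienced_B))
        self.state.B_hat = self.predict()


LEARNERS = {
    "averager": _Averager,
    "extrapolator": _Extrapolator,
}


def make_learner(name: str, params: Optional[LearnerParams] = None):
    try:
        cls = LEARNERS[name]
    except KeyError:
        raise KeyError(
            f"unknown learner {name!r}; registered: {sorted(LEARNERS)}"
        ) from None
    return cls(params or LearnerParams())


def load_learner_params(path: str) -> tuple[str, LearnerParams]:
    """Read ``(learner name, params)`` from a YAML/JSON block."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    name = raw.pop("name", "averager")
    return name, LearnerParams(**raw)


@dataclass
class SessionData:
    """One simulated subject: a schedule plus one record per trial."""

    schedule: Schedule
    records: list[TrialRecord]
    learner_name: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.records) != len(self.schedule):
            raise ValueError("one record per schedule trial is required")

    def clamp_records(self) -> list[TrialRecord]:
        return [
            r
            for r in self.records
            if r.spec is not None and r.spec.is_clamp
        ]

    # -- serialization ---------------------------------------------------
    # Layout: <dir>/schedule.csv, <dir>/records.csv (long format: one row
    # per sample), <dir>/manifest.json (learner, seed, per-trial gains).

    def to_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        self.schedule.to_csv(os.path.join(path, "schedule.csv"))
        frames = []
        for i, r in enumerate(self.records):
            n = len(r.vy)
            frames.append(
                pd.DataFrame(
                    {
                        "trial": i,
                        "sample": np.arange(n),
                        "t": np.arange(n) * r.dt,
                        "vy": r.vy,
                        "fx": r.fx,
                        "x": r.x,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            os.path.join(path, "records.csv"), index=False
        )
        manifest = {
            "learner_name": self.learner_name,
            "seed": self.seed,
            "dt": self.records[0].dt if self.records else None,
            "trials": [
                {"trial": i, "B_hat": r.B_hat, "B": _json_float(r.B)}
                for i, r in enumerate(self.records)
            ],
        }
        with open(
            os.path.join(path, "manifest.json"), "w", encoding="utf-8"
        ) as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def from_dir(cls, path: str) -> "SessionData":
        schedule = Schedule.from_csv(os.path.join(path, "schedule.csv"))
        with open(
            os.path.join(path, "manifest.json"), "r", encoding="utf-8"
        ) as fh:
            manifest = json.load(fh)
        df = pd.read_csv(os.path.join(path, "records.csv"))
        records = []
        meta = {m["trial"]: m for m in manifest["trials"]}
        for i, spec in enumerate(schedule.trials):
            g = df[df["trial"] == i]
            m = meta[i]
            records.append(
                TrialRecord(
                    spec=spec,
                    dt=manifest["dt"],
                    vy=g["vy"].to_numpy(),
                    fx=g["fx"].to_numpy(),
                    x=g["x"].to_numpy(),
                    B_hat=m["B_hat"],
                    B=float("nan") if m["B"] is None else m["B"],
                )
            )
        return cls(
            schedule=schedule,
            records=records,
            learner_name=manifest["learner_name"],
            seed=manifest["seed"],
        )


def _json_float(x: float) -> Optional[float]:
    return None if np.isnan(x) else float(x)


def run_subject(
    schedule: Schedule,
    learner: str = "averager",
    params: Optional[LearnerParams] = None,
    sim_config: Optional[SimConfig] = None,
    seed: int = 0,
) -> SessionData:
    """Simulate one synthetic subject over a full schedule.

    Every trial uses the same minimum-jerk reach.  Because the lateral
    plant is linear and every drive is a scalar multiple of the speed
    profile, each trial's response is the unit response (computed once
    per plant) scaled by the drive gain; this is exactly equivalent to
    integrating every trial separately (superposition) and makes whole
    cohorts cheap.  Motor noise perturbs the expressed gain per trial;
    the run is deterministic given ``seed``.
    """
    params = params or LearnerParams()
    sim_config = sim_config or SimConfig()
    subject = make_learner(learner, params)
    rng = np.random.default_rng(seed)

    profile = minjerk_profile(
        sim_config.distance, sim_config.duration, sim_config.dt
    )
    plant = sim_config.plant
    # unit responses: field plant driven by vy, clamp plant driven by vy
    x_field_unit, _ = kinematics.lateral_response(
        profile.vy, profile.dt, plant.mass, plant.arm_stiffness,
        plant.arm_damping,
    )
    x_clamp_unit, v_clamp_unit = kinematics.lateral_response(
        profile.vy,
        profile.dt,
        plant.mass,
        plant.arm_stiffness + plant.channel_stiffness,
        plant.arm_damping + plant.channel_damping,
        substeps=4,
    )
    wall_unit = (
        plant.channel_stiffness * x_clamp_unit
        + plant.channel_damping * v_clamp_unit
    )

    records: list[TrialRecord] = []
    for spec in schedule:
        B_hat = subject.predict()
        noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        B_used = B_hat * (1.0 + noise)
        if spec.trial_type is TrialType.error_clamp:
            rec = TrialRecord(
                spec=spec,
                dt=profile.dt,
                vy=profile.vy,
                fx=B_used * wall_unit,
                x=B_used * x_clamp_unit,
                B_hat=B_used,
                B=float("nan"),
            )
            subject.update(float("nan"), spec.trial_type)
        else:
            B = spec.B  # 0.0 on null-field trials
            rec = TrialRecord(
                spec=spec,
                dt=profile.dt,
                vy=profile.vy,
                fx=B_used * profile.vy,
                x=(B - B_used) * x_field_unit,
                B_hat=B_used,
                B=B,
            )
            subject.update(B, spec.trial_type)
        records.append(rec)
    return SessionData(
        schedule=schedule, records=records, learner_name=learner, seed=seed
    )
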