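"""Force-profile measurements on error-clamp trials.

The adaptation level on a clamp trial is quantified against the
"perfect" (full-compensatory) force ``F_FC(t) = B * v_y(t)`` — the
lateral force that would exactly cancel a field of amplitude ``B``
given that trial's speed profile:

* **adaptation coefficient** ``a`` — slope of the regression of the
  actually exerted force onto the perfect force.  The model is
  ``F_actual = a * F_FC`` with no intercept, so
  ``a = <F_actual, F_FC> / <F_FC, F_FC>`` (projection / regression
  through the origin); ``a = 1`` means complete adaptation.
* **correlation coefficient** ``r`` — Pearson correlation between
  exerted and perfect force (shape match, scale-free).
* **force at maximum speed** — the lateral force sampled at the instant
  of peak forward speed.  For velocity-proportional fields the peak
  force occurs at peak speed, so this coincides with the peak force;
  both are reported so the agreement can be checked.
* **movement error** — lateral displacement at the instant of peak
  speed.

Per-condition summaries average the per-clamp coefficients across the
clamp trials of each constant-phase condition (a pooled-profile
regression across the condition's clamps is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import TrialRecord
from .learners import SessionData
from .schedule import Phase

__all__ = [
    "AdaptationResult",
    "perfect_force",
    "force_at_max_speed",
    "peak_lateral_force",
    "adaptation_coefficient",
    "correlation_coefficient",
    "movement_error",
    "analyze_clamp_trial",
    "analyze_session",
    "summarize_conditions",
]


@dataclass
class AdaptationResult:
    """Per-trial adaptation measures (see module docstring for units)."""

    a: float
    r: float
    lf_max_speed: float  # N
    lf_peak: float  # N
    movement_error: float  # m


def perfect_force(B: float, vy: np.ndarray) -> np.ndarray:
    """Full-compensatory force profile ``B * vy`` (N)."""
    if B < 0:
        raise ValueError("B must be non-negative")
    return B * np.asarray(vy, dtype=float)


def _argmax_speed(vy: np.ndarray) -> int:
    vy = np.asarray(vy)
    if vy.size == 0:
        raise ValueError("empty speed series")
    # np.argmax returns the first maximal index: the documented tie-break
    return int(np.argmax(vy))


def force_at_max_speed(fx: np.ndarray, vy: np.ndarray) -> float:
    """Lateral force at the sample of maximum speed (earliest on ties)."""
    fx = np.asarray(fx)
    if len(fx) != len(vy):
        raise ValueError("fx and vy must share one length")
    return float(fx[_argmax_speed(vy)])


def peak_lateral_force(fx: np.ndarray) -> float:
    """Signed lateral force of largest magnitude."""
    fx = np.asarray(fx)
    if fx.size == 0:
        raise ValueError("empty force series")
    return float(fx[np.argmax(np.abs(fx))])


def adaptation_coefficient(
    F_actual: np.ndarray, F_FC: np.ndarray
) -> float:
    """Regression-through-origin slope of exerted onto perfect force.

    ``a = <F_actual, F_FC> / <F_FC, F_FC>``; invariant to any component
    of ``F_actual`` orthogonal to ``F_FC``.
    """
    F_actual = np.asarray(F_actual, dtype=float)
    F_FC = np.asarray(F_FC, dtype=float)
    if len(F_actual) != len(F_FC):
        raise ValueError("series must share one length")
    denom = float(np.dot(F_FC, F_FC))
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("perfect-force series has zero norm")
    return float(np.dot(F_actual, F_FC) / denom)


def correlation_coefficient(F_actual: np.ndarray, F_FC: np.ndarray) -> float:
    """Pearson correlation between exerted and perfect force."""
    F_actual = np.asarray(F_actual, dtype=float)
    F_FC = np.asarray(F_FC, dtype=float)
    if np.std(F_actual) == 0 or np.std(F_FC) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(stats.pearsonr(F_actual, F_FC).statistic)


def movement_error(x: np.ndarray, vy: np.ndarray) -> float:
    """Lateral displacement at the sample of maximum speed (m)."""
    x = np.asarray(x)
    if len(x) != len(vy):
        raise ValueError("x and vy must share one length")
    return float(x[_argmax_speed(vy)])


def analyze_clamp_trial(
    record: TrialRecord, B_reference: float
) -> AdaptationResult:
    """All adaptation measures for one error-clamp trial.

    ``B_reference`` is the field amplitude defining the perfect force
    (the block amplitude for constant-phase clamps).
    """
    F_FC = perfect_force(B_reference, record.vy)
    return AdaptationResult(
        a=adaptation_coefficient(record.fx, F_FC),
        r=correlation_coefficient(record.fx, F_FC),
        lf_max_speed=force_at_max_speed(record.fx, record.vy),
        lf_peak=peak_lateral_force(record.fx),
        movement_error=movement_error(record.x, record.vy),
    )


def analyze_session(session: SessionData) -> pd.DataFrame:
    """Per-clamp-trial measures for a whole session.

    One row per error-clamp trial with columns ``trial``, ``phase``,
    ``context`` (the condition amplitude for constant-phase clamps,
    ``"sequence"`` for sequence-trailing clamps, ``"random"`` for the
    remaining random-phase clamps), the adaptation measures, and
    ``sequence_id`` / ``block_id`` tags.  ``a`` and ``r`` are computed
    only where a reference amplitude exists (constant-phase clamps).
    """
    rows = []
    for i, rec in enumerate(session.records):
        spec = rec.spec
        if spec is None or not spec.is_clamp:
            continue
        if spec.block_id is not None:
            B_ref: Optional[float] = session.schedule.block_amplitude(
                spec.block_id
            )
            context = f"{B_ref:g}"
        elif spec.sequence_id is not None:
            B_ref, context = None, "sequence"
        else:
            B_ref, context = None, "random"
        if B_ref is not None:
            res = analyze_clamp_trial(rec, B_ref)
            a, r = res.a, res.r
        else:
            a = r = math.nan
        rows.append(
            {
                "trial": i,
                "phase": spec.phase.value,
                "context": context,
                "B_reference": math.nan if B_ref is None else B_ref,
                "a": a,
                "r": r,
                "lf_max_speed": force_at_max_speed(rec.fx, rec.vy),
                "lf_peak": peak_lateral_force(rec.fx),
                "movement_error": movement_error(rec.x, rec.vy),
                "sequence_id": spec.sequence_id,
                "block_id": spec.block_id,
            }
        )
    return pd.DataFrame(rows)


def summarize_conditions(
    session: SessionData, pooled: bool = False
) -> pd.DataFrame:
    """Per-condition summary over the constant-phase clamp trials.

    Default: compute ``a`` and ``r`` per clamp trial, then average the
    coefficients across each condition's clamps.  With ``pooled=True``
    the condition's clamp profiles are concatenated and a single
    regression / correlation is computed instead.
    """
    per_trial = analyze_session(session)
    const = per_trial[per_trial["phase"] == Phase.constant.value]
    rows = []
    for B_ref, g in const.groupby("B_reference"):
        row = {
            "B": B_ref,
            "n_clamps": len(g),
            "lf_max_speed": g["lf_max_speed"].mean(),
            "lf_peak": g["lf_peak"].mean(),
            "movement_error": g["movement_error"].mean(),
        }
        if pooled:
            fa, fc = [], []
            for t in g["trial"]:
                rec = session.records[int(t)]
                fa.append(rec.fx)
                fc.append(perfect_force(B_ref, rec.vy))
            fa, fc = np.concatenate(fa), np.concatenate(fc)
            row["a"] = adaptation_coefficient(fa, fc)
            row["r"] = correlation_coefficient(fa, fc)
        else:
            row["a"] = g["a"].mean()
            row["r"] = g["r"].mean()
        rows.append(row)
    return pd.DataFrame(rows).sort_values("B").reset_index(drop=True)
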