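"""Single-reach simulation: minimum-jerk kinematics, viscous curl
fields, and error-clamp (force-channel) dynamics.

The forward reach is modelled as a minimum-jerk point-to-point movement
sampled at 200 Hz.  A viscous curl field pushes the hand laterally with
a force proportional to forward speed, ``f_x(t) = B * v_y(t)``; the
learner opposes it with a feedforward force ``-B_hat * v_y(t)``.  The
lateral plant is a deliberately simple point mass with a linear arm
impedance (spring-damper), so any mismatch ``B - B_hat`` drives a
lateral displacement.  On error-clamp trials a stiff channel
spring-damper (1000 N/m, 50 Ns/m) suppresses lateral motion, and the
force pressed into the channel wall is recorded: it is the standard
high-accuracy readout of the learner's feedforward compensation.

Sign conventions: movements along +y, perturbing forces toward +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .schedule import TrialSpec

__all__ = [
    "VelocityProfile",
    "PlantParams",
    "SimConfig",
    "TrialRecord",
    "IntegrationError",
    "minjerk_profile",
    "field_force",
    "lateral_response",
    "simulate_field_trial",
    "simulate_clamp_trial",
]

#: Sampling interval matching the 200 Hz acquisition rate, in s.
DEFAULT_DT = 1.0 / 200.0


class IntegrationError(RuntimeError):
    """Raised when the fixed-step integrator would be unstable."""


@dataclass
class VelocityProfile:
    """Forward (y) speed and position of one reach, uniformly sampled."""

    dt: float
    vy: np.ndarray  # forward speed, m/s
    y: np.ndarray  # forward position, m

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.vy)) * self.dt

    @property
    def peak_speed(self) -> float:
        return float(np.max(self.vy))

    @property
    def distance(self) -> float:
        return float(self.y[-1] - self.y[0])


@dataclass
class PlantParams:
    """Lateral dynamics parameters.

    The hand/arm is a point mass with a linear impedance; the channel
    spring-damper is added on error-clamp trials only.  Channel defaults
    (1000 N/m, 50 Ns/m) are the standard force-channel constants; the
    arm values are a simple documented stand-in.
    """

    mass: float = 1.0  # kg
    arm_stiffness: float = 50.0  # N/m
    arm_damping: float = 10.0  # Ns/m
    channel_stiffness: float = 1000.0  # N/m
    channel_damping: float = 50.0  # Ns/m

    def __post_init__(self) -> None:
        for name in (
            "mass",
            "arm_stiffness",
            "arm_damping",
            "channel_stiffness",
            "channel_damping",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class SimConfig:
    """Reach geometry and plant used when simulating a session.

    The defaults (0.13 m in 0.45 s) give a peak speed of ~0.54 m/s.
    """

    distance: float = 0.13  # m
    duration: float = 0.45  # s
    dt: float = DEFAULT_DT  # s
    plant: PlantParams = field(default_factory=PlantParams)


@dataclass
class TrialRecord:
    """Time series and metadata of one simulated (or imported) trial.

    ``fx`` holds the learner's expressed lateral force: on field and
    null trials the feedforward force ``B_hat * vy``, on clamp trials
    the force measured at the channel wall.  ``B_hat`` is the gain the
    learner actually expressed on this trial (after motor noise).
    """

    spec: Optional[TrialSpec]
    dt: float
    vy: np.ndarray  # m/s
    fx: np.ndarray  # N
    x: np.ndarray  # m
    B_hat: float  # Ns/m
    B: float  # Ns/m (NaN on clamp trials)

    def __post_init__(self) -> None:
        if not (len(self.vy) == len(self.fx) == len(self.x)):
            raise ValueError("vy, fx and x must share one length")


def minjerk_profile(
    distance: float, duration: float, dt: float = DEFAULT_DT
) -> VelocityProfile:
    """Minimum-jerk speed profile for a point-to-point reach.

    The speed is the bell-shaped quintic ``v(t) = 30 D/T tau^2 (1-tau)^2``
    with ``tau = t/T``: zero at both endpoints, symmetric, peaking at
    ``1.875 D/T`` mid-movement.  Samples are rescaled so the trapezoidal
    integral of the discrete series equals ``distance`` exactly (the
    correction is O(dt^2), a few parts in 1e5 at 200 Hz).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if not 0 < dt < duration:
        raise ValueError("require 0 < dt < duration")
    n = int(round(duration / dt))
    tau = np.arange(n + 1) * dt / duration
    tau = np.clip(tau, 0.0, 1.0)
    vy = 30.0 * distance / duration * tau**2 * (1.0 - tau) ** 2
    vy *= distance / trapezoid(vy, dx=dt)
    y = cumulative_trapezoid(vy, dx=dt, initial=0.0)
    return VelocityProfile(dt=dt, vy=vy, y=y)


def field_force(B: float, profile: VelocityProfile) -> np.ndarray:
    """Lateral force of a viscous curl field: ``fx[t] = B * vy[t]``."""
    if B < 0:
        raise ValueError("field amplitude B must be non-negative")
    return B * profile.vy


def lateral_response(
    drive: np.ndarray,
    dt: float,
    mass: float,
    stiffness: float,
    damping: float,
    substeps: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``m x'' + c x' + k x = drive(t)`` from rest.

    Fixed-step RK4 with linear interpolation of the drive between
    samples; ``substeps`` subdivides each sample interval for stiff
    plants.  Returns ``(x, xdot)`` sampled at the input rate.  Raises
    :class:`IntegrationError` when the step would be unstable.
    """
    drive = np.asarray(drive, dtype=float)
    n = len(drive)
    h = dt / substeps
    # RK4 absolute-stability bound on the real axis is ~2.78/|lambda|.
    roots = np.roots([mass, damping, stiffness])
    lam = float(np.max(np.abs(roots)))
    if lam * h > 2.5:
        raise IntegrationError(
            f"step {h:.2e} s too large for plant eigenvalue {lam:.1f} 1/s; "
            "reduce dt or increase substeps"
        )
    x = np.zeros(n)
    v = np.zeros(n)
    xi, vi = 0.0, 0.0

    def acc(xx: float, vv: float, f: float) -> float:
        return (f - stiffness * xx - damping * vv) / mass

    for i in range(n - 1):
        f0, f1 = drive[i], drive[i + 1]
        for s in range(substeps):
            a0 = f0 + (f1 - f0) * (s / substeps)
            am = f0 + (f1 - f0) * ((s + 0.5) / substeps)
            a1 = f0 + (f1 - f0) * ((s + 1.0) / substeps)
            k1x = vi
            k1v = acc(xi, vi, a0)
            k2x = vi + 0.5 * h * k1v
            k2v = acc(xi + 0.5 * h * k1x, vi + 0.5 * h * k1v, am)
            k3x = vi + 0.5 * h * k2v
            k3v = acc(xi + 0.5 * h * k2x, vi + 0.5 * h * k2v, am)
            k4x = vi + h * k3v
            k4v = acc(xi + h * k3x, vi + h * k3v, a1)
            xi += h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            vi += h / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        x[i + 1] = xi
        v[i + 1] = vi
    return x, v


def simulate_field_trial(
    B_hat: float,
    B: float,
    profile: VelocityProfile,
    plant: Optional[PlantParams] = None,
    spec: Optional[TrialSpec] = None,
    substeps: int = 1,
) -> TrialRecord:
    """Simulate a force-field (or null-field, ``B = 0``) trial.

    The lateral plant is driven by the compensation mismatch
    ``(B - B_hat) * vy(t)``: a perfectly adapted learner (``B_hat = B``)
    moves in a straight line.  The recorded ``fx`` is the learner's
    feedforward force ``B_hat * vy``.
    """
    plant = plant or PlantParams()
    drive = (B - B_hat) * profile.vy
    x, _ = lateral_response(
        drive,
        profile.dt,
        plant.mass,
        plant.arm_stiffness,
        plant.arm_damping,
        substeps=substeps,
    )
    return TrialRecord(
        spec=spec,
        dt=profile.dt,
        vy=profile.vy.copy(),
        fx=B_hat * profile.vy,
        x=x,
        B_hat=B_hat,
        B=B,
    )


def simulate_clamp_trial(
    B_hat: float,
    profile: VelocityProfile,
    plant: Optional[PlantParams] = None,
    spec: Optional[TrialSpec] = None,
    substeps: int = 4,
) -> TrialRecord:
    """Simulate an error-clamp (force-channel) trial.

    The learner presses its feedforward force ``B_hat * vy(t)`` into a
    stiff channel spring-damper added to the arm impedance; lateral
    motion is nearly suppressed and the recorded ``fx`` is the force
    transmitted to the channel wall, ``k_ch x + c_ch x'``.
    """
    plant = plant or PlantParams()
    drive = B_hat * profile.vy
    x, xdot = lateral_response(
        drive,
        profile.dt,
        plant.mass,
        plant.arm_stiffness + plant.channel_stiffness,
        plant.arm_damping + plant.channel_damping,
        substeps=substeps,
    )
    wall = plant.channel_stiffness * x + plant.channel_damping * xdot
    return TrialRecord(
        spec=spec,
        dt=profile.dt,
        vy=profile.vy.copy(),
        fx=wall,
        x=x,
        B_hat=B_hat,
        B=math.nan,
    )
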