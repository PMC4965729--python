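"""The horizontal vestibulo-ocular reflex (hVOR) plant and scenarios.

The hVOR rotates the eye opposite to head rotation so that gaze -- and the
retinal image -- stays still.  Its simplest mechanical model is a first-order
viscoelastic plant for horizontal eye position ``x`` (degrees, relative to
the head) driven by the net motor-neuron command ``u``:

    dx/dt = -(kappa/rho) x + u / rho,

with viscosity ``kappa`` and elasticity ``rho`` (time constant
``rho/kappa``).  Performance is measured by the retinal slip

    y = dx/dt + dh/dt,

the sum of eye and head angular velocities; perfect gaze stabilisation is
``y = 0``.  The tracking reference is ``r = -h`` (eye mirrors the head), so
the feedback error rate equals the slip and a derivative controller on the
predicted error is the natural law.

`make_scenario` bundles plant, head motion, true-delay profile, controller
gains and estimator settings into the named experiments the simulator runs:

- ``zero_delay_baseline``: no sensory delay; the design condition for gains.
- ``compensated_constant_delay``: 10 ms constant delay, delay estimator and
  state predictor active (stable tracking).
- ``compensated_variable_delay``: slowly varying delay, full compensation
  (estimator tracks the drifting delay).
- ``uncompensated_delay``: same 10 ms delay, estimator and predictor
  disabled so the controller consumes the raw delayed error (oscillatory
  instability around the head velocity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .errors import ConfigError, DomainError
from .plant import LTVSystem

__all__ = [
    "HVORPlant",
    "HeadMotion",
    "DelayProfile",
    "Scenario",
    "SCENARIO_NAMES",
    "hvor_dynamics",
    "retinal_slip",
    "make_scenario",
]


@dataclass(frozen=True)
class HVORPlant:
    """First-order viscoelastic oculomotor plant."""

    kappa: float = 1.0  # viscosity (arbitrary consistent units)
    rho: float = 0.2  # elasticity; rho/kappa = 0.2 s oculomotor time constant
    x0: float = 0.0  # initial eye position relative to head, degrees

    def __post_init__(self) -> None:
        if not (self.kappa > 0.0 and self.rho > 0.0):
            raise DomainError("kappa and rho must be positive (stable decay)")

    @property
    def decay_rate(self) -> float:
        """``c = kappa / rho`` (1/s)."""
        return self.kappa / self.rho

    @property
    def time_constant(self) -> float:
        return self.rho / self.kappa

    def to_ltv(self) -> LTVSystem:
        """The plant as a scalar LTV system (constant coefficients)."""
        return LTVSystem.scalar(a=-self.decay_rate, b=1.0 / self.rho, x0=self.x0)


def hvor_dynamics(plant: HVORPlant, x: float, u: float) -> float:
    """Right-hand side ``dx/dt = -(kappa/rho) x + u / rho``."""
    if not (np.isfinite(x) and np.isfinite(u)):
        raise DomainError("hvor_dynamics requires finite x and u")
    return -plant.decay_rate * x + u / plant.rho


def retinal_slip(x_dot, h_dot):
    """Retinal-image slip velocity ``y = dx/dt + dh/dt`` (deg/s).

    Zero when the eye exactly counter-rotates the head.
    """
    return np.asarray(x_dot, dtype=float) + np.asarray(h_dot, dtype=float)


@dataclass(frozen=True)
class HeadMotion:
    """Head angular-velocity profile with its position antiderivative.

    ``h`` is needed because the tracking reference is ``r = -h``.
    """

    h_dot: Callable[[float], float]
    h: Callable[[float], float]
    description: str = ""

    @classmethod
    def sinusoid(cls, amplitude: float = 40.0, frequency: float = 1.0) -> "HeadMotion":
        """Sinusoidal head velocity ``A sin(2 pi f t)`` (deg/s), h(0) = 0."""
        w = 2.0 * math.pi * frequency
        return cls(
            h_dot=lambda t: amplitude * math.sin(w * t),
            h=lambda t: amplitude * (1.0 - math.cos(w * t)) / w,
            description=f"sinusoid {amplitude} deg/s at {frequency} Hz",
        )

    @classmethod
    def stationary(cls) -> "HeadMotion":
        return cls(h_dot=lambda t: 0.0, h=lambda t: 0.0, description="stationary head")


@dataclass(frozen=True)
class DelayProfile:
    """True sensory-delay profile ``tau(t)`` in seconds."""

    tau_of_t: Callable[[float], float]
    kind: str = "constant"

    def __call__(self, t: float) -> float:
        return self.tau_of_t(t)

    @classmethod
    def constant(cls, tau: float) -> "DelayProfile":
        if tau < 0.0:
            raise DomainError(f"delay must be >= 0, got {tau}")
        return cls(tau_of_t=lambda t, _v=float(tau): _v, kind="constant")

    @classmethod
    def zero(cls) -> "DelayProfile":
        return cls.constant(0.0)

    @classmethod
    def sinusoidal(
        cls, base: float = 0.010, amplitude: float = 0.004, frequency: float = 0.2
    ) -> "DelayProfile":
        """Slow sinusoidal drift ``base + amplitude * sin(2 pi f t)``."""
        if amplitude > base:
            raise DomainError("sinusoidal delay would go negative")
        w = 2.0 * math.pi * frequency
        return cls(
            tau_of_t=lambda t: base + amplitude * math.sin(w * t), kind="sinusoidal"
        )

    @classmethod
    def step(cls, before: float, after: float, at: float) -> "DelayProfile":
        if min(before, after) < 0.0:
            raise DomainError("delays must be >= 0")
        return cls(tau_of_t=lambda t: before if t < at else after, kind="step")


@dataclass(frozen=True)
class Scenario:
    """A reproducible closed-loop experiment definition."""

    name: str
    plant: HVORPlant
    head_motion: HeadMotion
    delay_profile: DelayProfile
    kd: float  # derivative gain of the hVOR control law
    derivative_filter_tau: float  # s; low-pass on the derivative term
    eta: float  # delay-estimator learning rate
    estimator_max_rate: Optional[float]  # s/s; slew limit on the estimate
    tau_max: float  # s; memory window / admissible-delay bound
    tau_hat0: float  # s; initial delay estimate
    estimator_enabled: bool
    predictor_enabled: bool
    u_max: Optional[float]  # motor-command saturation (units of u); None = none
    description: str = ""


# Defaults shared by all scenarios.  The plant time constant (200 ms), the
# head-motion sinusoid (40 deg/s at 1 Hz) and the variable-delay profile are
# configurable conventions; every closed-loop property tested is robust to
# them.  kd is designed on the zero-delay plant for <= 1 % steady-state slip.
# The estimator runs fast (eta) but slew-limited (max_rate): while the delay
# estimate is wrong the high-gain derivative loop is transiently unstable,
# so the estimate must settle before oscillation builds, and the rate cap
# keeps the explicit update stable whatever the transient amplitudes; the
# 10 ms constant-delay estimate converges well within ~2 s.
_PLANT = HVORPlant(kappa=1.0, rho=0.2, x0=0.0)
_KD = 40.0
_DFILT = 0.04
_ETA = 0.5
_EST_MAX_RATE = 0.5
_TAU_MAX = 0.05
_U_MAX = 500.0

SCENARIO_NAMES = (
    "zero_delay_baseline",
    "compensated_constant_delay",
    "compensated_variable_delay",
    "uncompensated_delay",
)


def make_scenario(name: str, **overrides) -> Scenario:
    """Build one of the named closed-loop experiments.

    Any `Scenario` field except ``name`` may be overridden by keyword.
    Unknown names raise `ConfigError` listing the valid ones.
    """
    common = dict(
        plant=_PLANT,
        head_motion=HeadMotion.sinusoid(40.0, 1.0),
        kd=_KD,
        derivative_filter_tau=_DFILT,
        eta=_ETA,
        estimator_max_rate=_EST_MAX_RATE,
        tau_max=_TAU_MAX,
        tau_hat0=_TAU_MAX / 2.0,
        estimator_enabled=True,
        predictor_enabled=True,
        u_max=_U_MAX,
    )
    if name == "zero_delay_baseline":
        # No delay to estimate: the initial hypothesis is zero, at which the
        # discrepancy vanishes identically and the loop is exactly the plain
        # no-delay feedback loop.
        params = dict(
            common,
            delay_profile=DelayProfile.zero(),
            tau_hat0=0.0,
            description="no sensory delay; gain-design condition",
        )
    elif name == "compensated_constant_delay":
        params = dict(
            common,
            delay_profile=DelayProfile.constant(0.010),
            description="10 ms constant delay, estimator + predictor active",
        )
    elif name == "compensated_variable_delay":
        params = dict(
            common,
            delay_profile=DelayProfile.sinusoidal(0.010, 0.004, 0.2),
            description="slowly drifting delay, estimator + predictor active",
        )
    elif name == "uncompensated_delay":
        params = dict(
            common,
            delay_profile=DelayProfile.constant(0.010),
            estimator_enabled=False,
            predictor_enabled=False,
            description="10 ms delay, raw delayed error fed to the controller",
        )
    else:
        raise ConfigError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    bad = set(overrides) - set(params)
    if bad:
        raise ConfigError(f"unknown scenario overrides: {sorted(bad)}")
    params.update(overrides)
    return Scenario(name=name, **params)
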