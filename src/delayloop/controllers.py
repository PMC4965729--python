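"""Feedback controllers acting on the predicted error.

All controllers consume the predicted performance error
``e_hat(t) = r(t) - x_hat(t)`` (reference minus predicted state).  The point
of the architecture is that gains can be designed on the delay-free plant:
once the predictor supplies ``x_hat ~= x``, the loop behaves as if there
were no delay.

Discrete realisation: the derivative term is a backward difference with an
optional first-order low-pass (time constant ``derivative_filter_tau``;
0 disables it); the integral term accumulates trapezoidally.  The filter
matters at high derivative gain, where an explicit unfiltered derivative
loop is discretely unstable even though the continuous law is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError, OrderingError, ShapeError

__all__ = [
    "ControllerGains",
    "ControllerState",
    "pid_control",
    "feedback_control",
    "hvor_derivative_control",
]


@dataclass(frozen=True)
class ControllerGains:
    """PID gains plus an optional static feedback matrix ``k``."""

    kp: float = 0.0
    kd: float = 0.0
    ki: float = 0.0
    k: Optional[np.ndarray] = None
    derivative_filter_tau: float = 0.0  # seconds; 0 = raw backward difference

    def __post_init__(self) -> None:
        for name in ("kp", "kd", "ki", "derivative_filter_tau"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"gain {name} must be finite, got {v}")
        if self.derivative_filter_tau < 0.0:
            raise DomainError("derivative_filter_tau must be >= 0")
        if self.k is not None:
            k = np.atleast_2d(np.asarray(self.k, dtype=float))
            if not np.all(np.isfinite(k)):
                raise DomainError("feedback gain matrix k must be finite")
            object.__setattr__(self, "k", k)


@dataclass(frozen=True)
class ControllerState:
    """Discrete controller memory: integral accumulator and previous error."""

    integral: float = 0.0
    previous_error: Optional[float] = None
    previous_time: Optional[float] = None
    derivative: float = 0.0  # filtered derivative estimate


def pid_control(
    state: ControllerState,
    e_hat: float,
    t: float,
    gains: ControllerGains,
) -> tuple[float, ControllerState]:
    """One step of the PID law ``u = Kp e + Kd de/dt + Ki int e``.

    Derivative by (optionally filtered) backward difference, integral by
    trapezoidal accumulation.  The first call emits no derivative or
    integral contribution.
    """
    e = float(e_hat)
    t = float(t)
    if state.previous_time is None:
        new = ControllerState(integral=0.0, previous_error=e, previous_time=t, derivative=0.0)
        return gains.kp * e, new
    dt = t - state.previous_time
    if dt <= 0.0:
        raise OrderingError(f"controller time must increase: {t} after {state.previous_time}")
    d_raw = (e - state.previous_error) / dt
    tf = gains.derivative_filter_tau
    alpha = dt / (tf + dt)  # tf = 0 -> alpha = 1 -> raw backward difference
    d = state.derivative + alpha * (d_raw - state.derivative)
    integral = state.integral + 0.5 * (e + state.previous_error) * dt
    u = gains.kp * e + gains.kd * d + gains.ki * integral
    return u, ControllerState(
        integral=integral, previous_error=e, previous_time=t, derivative=d
    )


def feedback_control(e_hat, gains: ControllerGains):
    """Stateless static feedback ``u = K e_hat``."""
    if gains.k is None:
        raise DomainError("feedback_control requires gains.k")
    e = np.atleast_1d(np.asarray(e_hat, dtype=float))
    if gains.k.shape[1] != e.shape[0]:
        raise ShapeError(f"K shape {gains.k.shape} incompatible with error shape {e.shape}")
    return gains.k @ e


def hvor_derivative_control(
    state: ControllerState,
    e_hat: float,
    t: float,
    kd: float,
    derivative_filter_tau: float = 0.0,
) -> tuple[float, ControllerState]:
    """Pure derivative law ``u = Kd * d e_hat/dt`` used by the hVOR loop.

    With the reference ``r = -h`` this drives the rate of the tracking
    error -- the retinal slip -- toward zero.
    """
    gains = ControllerGains(kd=kd, derivative_filter_tau=derivative_filter_tau)
    return pid_control(state, e_hat, t, gains)
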