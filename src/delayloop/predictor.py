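"""Prediction of the current state from a delayed measurement.

Given the delayed measurement and the stored motor-command history, the
current state is reconstructed by propagating the measurement forward along
the plant flow and adding the contribution of the commands issued since:

    x_hat(t) = G(t) G^-1(t - tau_hat) * x_meas
             + G(t) * integral_{t - tau_hat}^{t} G^-1(s) B(s) u(s) ds.

The sensed signal is physically ``x(t - tau)``, but the controller cannot
distinguish the true lag from its own hypothesis, so the measurement is
relabelled to lag ``tau_hat`` before propagation -- the only consistent
reading.  When ``tau_hat = tau`` and the internal model is exact, the
prediction reproduces ``x(t)`` to integration tolerance; the prediction
error is continuous in ``tau_hat - tau`` and vanishes with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .buffer import HistoryBuffer
from .errors import DomainError
from .plant import LTVSystem, TransitionOperator

__all__ = ["PredictedState", "predict_state", "hvor_predict_state"]


@dataclass(frozen=True)
class PredictedState:
    """A predicted current state and the delay hypothesis that produced it."""

    x_hat: np.ndarray
    t: float
    tau_hat_used: float

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x_hat, dtype=float))
        if not np.all(np.isfinite(x)):
            raise DomainError("predicted state contains non-finite entries")
        object.__setattr__(self, "x_hat", x)

    @property
    def scalar(self) -> float:
        return float(self.x_hat[0])


def predict_state(
    system: LTVSystem,
    transition: TransitionOperator,
    measured_delayed_state,
    u_buffer: HistoryBuffer,
    tau_hat: float,
    t: float,
) -> PredictedState:
    """Propagate a delayed measurement to the current time.

    The command integral is evaluated by the trapezoidal rule on the
    buffered ``u`` samples over ``[t - tau_hat, t]``; insufficient history
    raises `OutOfWindowError`.  ``tau_hat = 0`` is an exact passthrough of
    the measurement.
    """
    t = float(t)
    tau_hat = float(tau_hat)
    if tau_hat < 0.0:
        raise DomainError(f"tau_hat must be >= 0, got {tau_hat}")
    meas = np.atleast_1d(np.asarray(measured_delayed_state, dtype=float))
    if tau_hat == 0.0:
        return PredictedState(x_hat=meas, t=t, tau_hat_used=0.0)
    t0 = t - tau_hat
    phi = transition.propagator(t0, t)
    ts, us = u_buffer.segment(t0, t)
    us = np.atleast_2d(us.T).T  # (n_samples, input_dim)
    vals = np.empty((ts.size, system.state_dim))
    for i, s in enumerate(ts):
        # Phi(s -> t) B(s) u(s): propagating each command's effect to t
        vals[i] = transition.propagator(s, t) @ system.B_mat(s) @ us[i]
    x_hat = phi @ meas + np.trapezoid(vals, ts, axis=0)
    return PredictedState(x_hat=x_hat, t=t, tau_hat_used=tau_hat)


def hvor_predict_state(
    measured: float,
    u_buffer: HistoryBuffer,
    kappa: float,
    rho: float,
    tau_hat: float,
    t: float,
) -> PredictedState:
    """Closed-form predictor for the scalar oculomotor plant.

    With ``G(t) = exp(-c t)``, ``c = kappa/rho``:

        x_hat(t) = exp(-c * tau_hat) * x_meas
                 + integral_{t - tau_hat}^{t} exp(-c (t - s)) u(s) / rho ds.

    Note the decay factor ``exp(-c tau_hat)`` on the measured term: the
    measurement is older than the prediction time, so the homogeneous part
    decays forward in time.  Equals :func:`predict_state` on the same
    inputs to quadrature tolerance.
    """
    t = float(t)
    tau_hat = float(tau_hat)
    if tau_hat < 0.0:
        raise DomainError(f"tau_hat must be >= 0, got {tau_hat}")
    if tau_hat == 0.0:
        return PredictedState(x_hat=np.array([float(measured)]), t=t, tau_hat_used=0.0)
    c = kappa / rho
    ts, us = u_buffer.segment(t - tau_hat, t)
    kernel = np.exp(-c * (t - ts)) * np.asarray(us, dtype=float).reshape(ts.size) / rho
    x_hat = math.exp(-c * tau_hat) * float(measured) + float(np.trapezoid(kernel, ts))
    return PredictedState(x_hat=np.array([x_hat]), t=t, tau_hat_used=tau_hat)
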