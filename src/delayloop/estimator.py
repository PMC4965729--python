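"""Online estimation of the sensory delay by gradient descent.

The controller never observes the true delay ``tau``; it only receives the
delayed measurement ``x(t - tau)``.  Maintaining an internal hypothesis
``tau_hat``, it reconstructs what the internal forward model says the state
was at lag ``tau_hat`` and forms the discrepancy

    zeta = x(t - tau) - x_model(t - tau_hat),

then descends the squared discrepancy:

    d tau_hat / dt = -eta * zeta * d zeta / d tau_hat,

clamped to the admissible interval ``[0, tau_max]`` imposed by bounded
memory.  When the forward model is exact, ``zeta`` vanishes identically at
``tau_hat = tau``, making the true delay a fixed point of the update.

Gradient derivation
-------------------
Differentiating the delayed variation-of-constants solution with respect to
the hypothesised lag collapses, by the chain rule and the Leibniz rule on
the integral's moving endpoint, to

    d zeta / d tau_hat = -d/d tau_hat [ x(t - tau_hat) ]
                       = + dx/dt evaluated at (t - tau_hat)
                       = A(t - tau_hat) x(t - tau_hat) + B(t - tau_hat) u(t - tau_hat).

The expanded operator form (terms in dG/d tau_hat and the integrand at the
moving endpoint) is algebraically the same quantity;
:func:`delay_gradient_full_history` computes it through that route from the
full input history and is pinned against both the buffered route and central
finite differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .buffer import HistoryBuffer
from .errors import DomainError, ShapeError
from .plant import LTVSystem, TransitionOperator, solve_state

__all__ = [
    "DelayEstimate",
    "estimation_error",
    "delay_gradient",
    "delay_gradient_full_history",
    "update_delay_estimate",
    "hvor_delay_update",
]


@dataclass(frozen=True)
class DelayEstimate:
    """The internal delay hypothesis and its learning-rule parameters.

    Attributes
    ----------
    tau_hat
        Current delay estimate, seconds; always within ``[0, tau_max]``.
    eta
        Learning rate of the gradient-descent rule (1 / (s * state-unit^2)).
    tau_max
        Upper bound of the admissible interval (memory window), seconds.
    last_error
        Most recent discrepancy ``zeta`` (state units), diagnostic.
    """

    tau_hat: float
    eta: float
    tau_max: float
    last_error: float = 0.0
    max_rate: Optional[float] = None  # s/s; slew limit on d tau_hat/dt

    def __post_init__(self) -> None:
        if not self.eta > 0.0:
            raise DomainError(f"learning rate eta must be > 0, got {self.eta}")
        if self.max_rate is not None and not self.max_rate > 0.0:
            raise DomainError(f"max_rate must be > 0 when set, got {self.max_rate}")
        if not 0.0 < self.tau_max < np.inf:
            raise DomainError(f"tau_max must be positive and finite, got {self.tau_max}")
        if not 0.0 <= self.tau_hat <= self.tau_max:
            raise DomainError(
                f"tau_hat={self.tau_hat} outside admissible [0, {self.tau_max}]"
            )


def estimation_error(measured_delayed_state, model_state_at_tau_hat):
    """Discrepancy ``zeta`` between the sensed and model-reconstructed state.

    The first argument is the sensed signal ``x(t - tau)`` (the true lag is
    never read); the second is the internal model's state at the
    hypothesised lag ``tau_hat``.
    """
    a = np.atleast_1d(np.asarray(measured_delayed_state, dtype=float))
    b = np.atleast_1d(np.asarray(model_state_at_tau_hat, dtype=float))
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: measured {a.shape} vs model {b.shape}")
    return a - b


def delay_gradient(
    system: LTVSystem,
    u_buffer: HistoryBuffer,
    x_buffer: HistoryBuffer,
    tau_hat: float,
    t: float,
) -> np.ndarray:
    """Sensitivity ``d zeta / d tau_hat`` from buffered histories.

    Samples the model-state and motor-command buffers at ``t - tau_hat`` and
    returns the plant right-hand side there (see module docstring for the
    derivation).  Raises `OutOfWindowError` if ``tau_hat`` exceeds the
    buffered window.
    """
    tq = float(t) - float(tau_hat)
    x_m = np.atleast_1d(np.asarray(x_buffer.sample(tq), dtype=float))
    u_q = np.atleast_1d(np.asarray(u_buffer.sample(tq), dtype=float))
    return system.A_mat(tq) @ x_m + system.B_mat(tq) @ u_q


def delay_gradient_full_history(
    system: LTVSystem,
    transition: TransitionOperator,
    u: Callable[[float], "float | np.ndarray"],
    tau_hat: float,
    t: float,
    dt: float = 1e-4,
) -> np.ndarray:
    """``d zeta / d tau_hat`` via the expanded transition-operator form.

    Reconstructs ``x(t - tau_hat)`` from the full input history through the
    delayed variation-of-constants solution and assembles the derivative
    from the operator term ``(dG/d tau_hat)(...)`` plus the moving-endpoint
    term ``B u`` at ``t - tau_hat``.  Exists as an independent route to the
    same quantity as :func:`delay_gradient`; the two are equal up to
    quadrature tolerance.
    """
    tq = float(t) - float(tau_hat)
    if tq < 0.0:
        raise DomainError(f"tau_hat={tau_hat} exceeds current time t={t}")
    # dG(t - tau_hat)/d tau_hat = -A(tq) G(tq); applied to [x0 + int G^-1 B u]
    # it contributes -A(tq) x(tq); the moving endpoint of the input integral
    # contributes -B(tq) u(tq).  d zeta/d tau_hat = -(d/d tau_hat) x(tq)
    # flips both signs.
    x_q = solve_state(system, u, tq, dt=dt, transition=transition)
    u_q = np.atleast_1d(np.asarray(u(tq), dtype=float))
    return system.A_mat(tq) @ x_q + system.B_mat(tq) @ u_q


def update_delay_estimate(
    est: DelayEstimate,
    zeta,
    gradient,
    dt: float,
) -> DelayEstimate:
    """One explicit-Euler step of the gradient-descent delay update.

    ``tau_hat <- clamp(tau_hat - eta * <zeta, d zeta/d tau_hat> * dt, 0, tau_max)``.
    For vector states the product is the inner product, i.e. the gradient of
    ``0.5 * ||zeta||^2`` with respect to ``tau_hat``.

    If ``est.max_rate`` is set, the descent rate ``d tau_hat/dt`` is slew-
    limited to ``[-max_rate, +max_rate]`` before the Euler step.  Away from
    the optimum the rule then behaves like sign-gradient descent at a fixed,
    signal-amplitude-independent speed, which keeps the explicit
    discretisation stable when transient oscillations make
    ``eta * |zeta * gradient|`` momentarily huge; near the optimum the cap
    is inactive and the update is the plain gradient law.
    """
    if not dt > 0.0:
        raise DomainError(f"dt must be > 0, got {dt}")
    z = np.atleast_1d(np.asarray(zeta, dtype=float))
    g = np.atleast_1d(np.asarray(gradient, dtype=float))
    if z.shape != g.shape:
        raise ShapeError(f"zeta shape {z.shape} vs gradient shape {g.shape}")
    rate = est.eta * float(z @ g)
    if est.max_rate is not None:
        rate = min(max(rate, -est.max_rate), est.max_rate)
    tau = min(max(est.tau_hat - rate * dt, 0.0), est.tau_max)
    return replace(est, tau_hat=tau, last_error=float(np.linalg.norm(z)))


def hvor_delay_update(
    est: DelayEstimate,
    kappa: float,
    rho: float,
    measured: float,
    u_buffer: HistoryBuffer,
    x_buffer: HistoryBuffer,
    t: float,
    dt: float,
) -> DelayEstimate:
    """Delay update specialised to the scalar oculomotor plant.

    With ``G(t) = exp(-(kappa/rho) t)`` the gradient reduces to the scalar
    plant right-hand side ``-(kappa/rho) x + u/rho`` at the hypothesised
    lag; numerically identical to the general path on the same buffers.
    """
    tq = float(t) - est.tau_hat
    x_m = float(np.atleast_1d(x_buffer.sample(tq))[0])
    u_q = float(np.atleast_1d(u_buffer.sample(tq))[0])
    zeta = float(measured) - x_m
    grad = -(kappa / rho) * x_m + u_q / rho
    return update_delay_estimate(est, zeta, grad, dt)
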