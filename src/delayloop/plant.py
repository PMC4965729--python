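"""Linear time-varying plant and its transition operator.

The sensorimotor plant is modelled as the linear time-varying (LTV) system

    dx/dt = A(t) x(t) + B(t) u(t),        x(0) = x0,

where ``x`` is the sensed state (e.g. eye position relative to the head, in
degrees), ``u`` the motor command, ``A(t)`` the state Jacobian and ``B(t)``
the control Jacobian.  The variation-of-constants solution is

    x(t) = G(t) x0 + G(t) * integral_0^t G^-1(s) B(s) u(s) ds,

with ``G`` the transition operator (fundamental matrix) of the homogeneous
dynamics, ``G(0) = I``.  For scalar plants -- and more generally whenever
``A(t)`` commutes with its own integral -- ``G(t) = exp(integral_0^t A)``
exactly.  For general matrices that exponential-of-integral formula is not
exact, so :func:`transition_operator` instead integrates the fundamental
matrix ODE ``dG/dt = A(t) G``, ``G(0) = I``; the two constructions coincide
in the commuting case, which covers every plant used by the oculomotor
scenarios.

All quantities carry seconds for time; state and input units are
task-specific and never inspected here.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, PlantEvaluationError, ShapeError

__all__ = [
    "LTVSystem",
    "TransitionOperator",
    "transition_operator",
    "solve_state",
    "delayed_state",
]


@dataclass(frozen=True)
class LTVSystem:
    """The plant ``dx/dt = A(t) x + B(t) u`` with initial state ``x0``.

    Parameters
    ----------
    state_dim, input_dim
        Positive dimensions of the state and input vectors.
    A, B
        Callables of time (seconds) returning matrices of shape
        ``(state_dim, state_dim)`` and ``(state_dim, input_dim)``.
        Must return finite entries for every queried ``t >= 0``.
    x0
        State vector at ``t = 0``.
    """

    state_dim: int
    input_dim: int
    A: Callable[[float], np.ndarray]
    B: Callable[[float], np.ndarray]
    x0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.state_dim < 1 or self.input_dim < 1:
            raise ShapeError("state_dim and input_dim must be >= 1")
        x0 = np.zeros(self.state_dim) if self.x0 is None else np.atleast_1d(
            np.asarray(self.x0, dtype=float)
        )
        if x0.shape != (self.state_dim,):
            raise ShapeError(f"x0 has shape {x0.shape}, expected ({self.state_dim},)")
        if not np.all(np.isfinite(x0)):
            raise DomainError("x0 must be finite")
        object.__setattr__(self, "x0", x0)
        # fail fast on mis-declared shapes
        self.A_mat(0.0)
        self.B_mat(0.0)

    def A_mat(self, t: float) -> np.ndarray:
        """Evaluate ``A(t)`` with shape and finiteness checks."""
        return self._eval(self.A, t, (self.state_dim, self.state_dim), "A")

    def B_mat(self, t: float) -> np.ndarray:
        """Evaluate ``B(t)`` with shape and finiteness checks."""
        return self._eval(self.B, t, (self.state_dim, self.input_dim), "B")

    def _eval(self, fn, t, shape, name):
        m = np.atleast_2d(np.asarray(fn(float(t)), dtype=float))
        if m.shape != shape:
            raise PlantEvaluationError(
                f"{name}({t}) has shape {m.shape}, expected {shape}"
            )
        if not np.all(np.isfinite(m)):
            raise PlantEvaluationError(f"{name}({t}) contains non-finite entries")
        return m

    @property
    def is_scalar(self) -> bool:
        return self.state_dim == 1 and self.input_dim == 1

    @classmethod
    def scalar(
        cls,
        a: "float | Callable[[float], float]",
        b: "float | Callable[[float], float]",
        x0: float = 0.0,
    ) -> "LTVSystem":
        """Build a scalar plant from scalar coefficients or callables."""
        a_fn = a if callable(a) else (lambda t, _a=float(a): _a)
        b_fn = b if callable(b) else (lambda t, _b=float(b): _b)
        return cls(
            state_dim=1,
            input_dim=1,
            A=lambda t: np.array([[a_fn(t)]], dtype=float),
            B=lambda t: np.array([[b_fn(t)]], dtype=float),
            x0=np.array([float(x0)]),
        )


class TransitionOperator:
    """Fundamental solution ``G(t)`` of ``dG/dt = A(t) G``, ``G(0) = I``.

    Provides ``evaluate(t)``, ``evaluate_inverse(t)`` and the two-time
    propagator ``propagator(t_from, t_to) = G(t_to) G(t_from)^{-1}`` that maps
    a state at ``t_from`` to ``t_to`` along the homogeneous flow.
    Integration extends lazily as larger times are queried.

    Scalar plants are tracked in log space, ``z(t) = integral_0^t a``, so
    strongly decaying plants stay accurate (``G = e^z`` never underflows the
    relative precision of ``z``) and propagators are simple exponential
    differences.
    """

    def __init__(self, system: LTVSystem, rtol: float = 1e-11, atol: float = 1e-13):
        self._sys = system
        self._rtol = rtol
        self._atol = atol
        self._scalar = system.state_dim == 1
        self._ends: list[float] = [0.0]
        self._sols: list = []
        n = system.state_dim
        self._y_end = (
            np.zeros(1) if self._scalar else np.eye(n).ravel()
        )

    # -- internal -----------------------------------------------------------
    def _rhs(self, t, y):
        A = self._sys.A_mat(t)
        if self._scalar:
            return [float(A[0, 0])]
        n = self._sys.state_dim
        return (A @ y.reshape(n, n)).ravel()

    def _extend(self, t: float) -> None:
        while self._ends[-1] < t:
            t0 = self._ends[-1]
            t1 = max(t, t0 * 1.5 + 1.0)
            res = solve_ivp(
                self._rhs,
                (t0, t1),
                self._y_end,
                dense_output=True,
                rtol=self._rtol,
                atol=self._atol,
                method="DOP853",
            )
            if not res.success:  # pragma: no cover - defensive
                raise PlantEvaluationError(
                    f"transition-operator integration failed near t={t0}: {res.message}"
                )
            self._sols.append(res.sol)
            self._ends.append(t1)
            self._y_end = res.y[:, -1]

    def _raw(self, t: float) -> np.ndarray:
        t = float(t)
        if t < 0.0:
            raise DomainError(f"transition operator queried at negative time t={t}")
        if t == 0.0:
            return np.zeros(1) if self._scalar else np.eye(self._sys.state_dim).ravel()
        self._extend(t)
        i = bisect.bisect_left(self._ends, t, lo=1) - 1
        return np.asarray(self._sols[i](t))

    # -- public -------------------------------------------------------------
    def log_scale(self, t: float) -> float:
        """Scalar plants only: ``z(t) = integral_0^t a(s) ds`` with ``G = e^z``."""
        if not self._scalar:
            raise ShapeError("log_scale is defined for scalar plants only")
        return float(self._raw(t)[0])

    def log_scale_array(self, ts: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`log_scale` over a sorted array of times >= 0."""
        if not self._scalar:
            raise ShapeError("log_scale_array is defined for scalar plants only")
        ts = np.asarray(ts, dtype=float)
        if ts.size == 0:
            return np.empty(0)
        if ts[0] < 0.0:
            raise DomainError("transition operator queried at negative time")
        self._extend(float(ts[-1]))
        out = np.empty(ts.shape)
        for i, (t0, t1) in enumerate(zip(self._ends[:-1], self._ends[1:])):
            mask = (ts > t0) & (ts <= t1) if i else (ts >= t0) & (ts <= t1)
            if np.any(mask):
                out[mask] = self._sols[i](ts[mask])[0]
        out[ts == 0.0] = 0.0
        return out

    def evaluate(self, t: float) -> np.ndarray:
        """Return ``G(t)`` as a ``(state_dim, state_dim)`` matrix."""
        if self._scalar:
            return np.array([[math.exp(self.log_scale(t))]])
        n = self._sys.state_dim
        return self._raw(t).reshape(n, n)

    def evaluate_inverse(self, t: float) -> np.ndarray:
        """Return ``G(t)^{-1}``."""
        if self._scalar:
            return np.array([[math.exp(-self.log_scale(t))]])
        return np.linalg.inv(self.evaluate(t))

    def propagator(self, t_from: float, t_to: float) -> np.ndarray:
        """Return ``G(t_to) G(t_from)^{-1}`` (flow map from t_from to t_to)."""
        if self._scalar:
            return np.array(
                [[math.exp(self.log_scale(t_to) - self.log_scale(t_from))]]
            )
        return self.evaluate(t_to) @ self.evaluate_inverse(t_from)


def transition_operator(
    system: LTVSystem, rtol: float = 1e-11, atol: float = 1e-13
) -> TransitionOperator:
    """Construct the transition operator ``G`` for ``system``.

    ``G`` is computed as the fundamental matrix of ``dG/dt = A(t) G`` rather
    than as ``exp(integral A)``: the exponential-of-integral form is exact
    only when ``A(t)`` commutes with its own integral (always true for scalar
    plants, where the two agree to integration tolerance).
    """
    return TransitionOperator(system, rtol=rtol, atol=atol)


def _u_values(system: LTVSystem, u, grid: np.ndarray) -> np.ndarray:
    """Evaluate the control signal on a grid, validating domain and finiteness."""
    vals = np.empty((grid.size, system.input_dim))
    for i, s in enumerate(grid):
        try:
            v = u(float(s))
        except Exception as exc:
            raise DomainError(f"control signal undefined at t={s}: {exc}") from exc
        v = np.atleast_1d(np.asarray(v, dtype=float))
        if v.shape != (system.input_dim,):
            raise ShapeError(
                f"u({s}) has shape {v.shape}, expected ({system.input_dim},)"
            )
        if not np.all(np.isfinite(v)):
            raise DomainError(f"control signal non-finite at t={s}")
        vals[i] = v
    return vals


def solve_state(
    system: LTVSystem,
    u: Callable[[float], "float | Sequence[float]"],
    t: float,
    dt: float = 1e-4,
    transition: "TransitionOperator | None" = None,
) -> np.ndarray:
    """Solve the plant at time ``t`` via the variation-of-constants formula.

    The input integral ``G(t) * integral_0^t G^-1(s) B(s) u(s) ds`` is
    evaluated by the composite trapezoidal rule on a uniform grid of step
    ``<= dt``, so the result converges at second order under step refinement.

    Parameters
    ----------
    u
        Control signal, callable on all of ``[0, t]``; scalar returns are
        promoted for scalar plants.
    dt
        Target quadrature step (seconds).
    transition
        Optionally reuse a previously built transition operator.
    """
    t = float(t)
    if t < 0.0:
        raise DomainError(f"t must be >= 0, got {t}")
    if t == 0.0:
        return system.x0.copy()
    G = transition if transition is not None else transition_operator(system)
    n = max(2, int(math.ceil(t / dt)))
    grid = np.linspace(0.0, t, n + 1)
    uv = _u_values(system, u, grid)
    if system.state_dim == 1:
        # vectorised scalar path: weights e^{z(t)-z(s)} are stable for decay
        z = G.log_scale_array(grid)
        b = np.array([system.B_mat(s)[0] @ uv[i] for i, s in enumerate(grid)])
        integrand = np.exp(z[-1] - z) * b
        x_t = math.exp(z[-1]) * system.x0[0] + np.trapezoid(integrand, grid)
        return np.array([x_t])
    Gt = G.evaluate(t)
    integrand = np.empty((grid.size, system.state_dim))
    for i, s in enumerate(grid):
        integrand[i] = G.evaluate_inverse(s) @ system.B_mat(s) @ uv[i]
    return Gt @ system.x0 + Gt @ np.trapezoid(integrand, grid, axis=0)


def delayed_state(
    system: LTVSystem,
    u: Callable[[float], "float | Sequence[float]"],
    t: float,
    lag: float,
    dt: float = 1e-4,
    transition: "TransitionOperator | None" = None,
) -> np.ndarray:
    """State at ``t - lag``: the delayed solution of the plant.

    This is what a sensory pathway with transmission delay ``lag`` delivers
    at time ``t``, and what the delay estimator reconstructs internally at
    its hypothesised lag.  Requires ``0 <= lag <= t``.
    """
    lag = float(lag)
    if lag < 0.0 or lag > float(t):
        raise DomainError(f"lag must satisfy 0 <= lag <= t, got lag={lag}, t={t}")
    return solve_state(system, u, float(t) - lag, dt=dt, transition=transition)
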