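import math

import numpy as np
import pytest

from _oracles import rk4_solve
from delayloop import (
    DomainError,
    LTVSystem,
    PlantEvaluationError,
    ShapeError,
    delayed_state,
    solve_state,
    transition_operator,
)


def u_sin(t):
    return 2.0 * math.sin(3.0 * t + 0.4)


@pytest.fixture(scope="module")
def ltv_scalar():
    """Smoothly time-varying stable scalar plant."""
    return LTVSystem.scalar(
        a=lambda t: -2.0 + 0.5 * math.sin(2.0 * t),
        b=lambda t: 1.0 + 0.3 * math.cos(t),
        x0=0.7,
    )


class TestTransitionOperator:
    def test_zero_dynamics_gives_identity_flow(self):
        G = transition_operator(LTVSystem.scalar(a=0.0, b=1.0))
        for t in (0.0, 0.5, 2.0):
            assert G.evaluate(t)[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_decay_gives_scalar_exponential(self):
        c = 5.0  # hVOR-style decay kappa/rho
        G = transition_operator(LTVSystem.scalar(a=-c, b=1.0))
        assert G.evaluate(0.0)[0, 0] == 1.0
        for t in (0.1, 1.0, 3.0):
            assert G.evaluate(t)[0, 0] == pytest.approx(math.exp(-c * t), rel=1e-9)

    def test_sinusoidal_coefficient_matches_exponential_of_integral(self):
        # a(t) = sin t integrates to 1 - cos t
        G = transition_operator(LTVSystem.scalar(a=math.sin, b=1.0))
        for t in (0.5, 1.0, 2.0):
            expected = math.exp(1.0 - math.cos(t))
            assert G.evaluate(t)[0, 0] == pytest.approx(expected, rel=1e-10)
            # and the numerical fundamental-matrix oracle agrees
            oracle = rk4_solve(lambda s, g: np.array([math.sin(s)]) * g, [1.0], 0.0, t, 4000)
            assert G.evaluate(t)[0, 0] == pytest.approx(oracle[0], rel=1e-8)

    def test_inverse_is_pointwise_inverse(self):
        G = transition_operator(LTVSystem.scalar(a=lambda t: -1.0 - t, b=1.0))
        for t in (0.0, 0.3, 1.7):
            assert G.evaluate(t)[0, 0] * G.evaluate_inverse(t)[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_commuting_matrix_fundamental_agrees_with_exponential_of_integral(self):
        # diagonal A(t) commutes with its integral: closed form available
        A = lambda t: np.diag([math.sin(t), -2.0])
        sys2 = LTVSystem(state_dim=2, input_dim=1, A=A, B=lambda t: np.ones((2, 1)), x0=[1.0, 1.0])
        G = transition_operator(sys2)
        for t in (0.5, 1.5):
            expected = np.diag([math.exp(1.0 - math.cos(t)), math.exp(-2.0 * t)])
            assert np.allclose(G.evaluate(t), expected, rtol=1e-8)

    def test_negative_time_rejected(self):
        G = transition_operator(LTVSystem.scalar(a=-1.0, b=1.0))
        with pytest.raises(DomainError):
            G.evaluate(-0.1)

    def test_non_finite_dynamics_reported_with_time(self):
        sys_bad = LTVSystem.scalar(a=lambda t: math.nan if t > 0.5 else -1.0, b=1.0)
        with pytest.raises(PlantEvaluationError, match="A\\("):
            transition_operator(sys_bad).evaluate(1.0)


class TestSolveState:
    def test_homogeneous_solution_is_exponential(self):
        sys1 = LTVSystem.scalar(a=-1.5, b=1.0, x0=2.0)
        x = solve_state(sys1, lambda t: 0.0, 1.2)
        assert x[0] == pytest.approx(2.0 * math.exp(-1.5 * 1.2), rel=1e-9)

    def test_pure_integrator_ramps_linearly(self):
        sys1 = LTVSystem.scalar(a=0.0, b=1.0, x0=0.3)
        x = solve_state(sys1, lambda t: 4.0, 2.0)
        assert x[0] == pytest.approx(0.3 + 4.0 * 2.0, rel=1e-9)

    def test_matches_runge_kutta_oracle(self, ltv_scalar):
        x = solve_state(ltv_scalar, u_sin, 1.7, dt=1e-4)
        f = lambda t, v: ltv_scalar.A_mat(t) @ v + ltv_scalar.B_mat(t) @ np.atleast_1d(u_sin(t))
        oracle = rk4_solve(f, ltv_scalar.x0, 0.0, 1.7, 20000)
        assert abs(x[0] - oracle[0]) / abs(oracle[0]) <= 1e-6

    def test_quadrature_error_decreases_under_refinement(self, ltv_scalar):
        f = lambda t, v: ltv_scalar.A_mat(t) @ v + ltv_scalar.B_mat(t) @ np.atleast_1d(u_sin(t))
        oracle = rk4_solve(f, ltv_scalar.x0, 0.0, 1.0, 20000)[0]
        errs = [abs(solve_state(ltv_scalar, u_sin, 1.0, dt=dt)[0] - oracle) for dt in (4e-3, 1e-3, 2.5e-4)]
        assert errs[0] > errs[1] > errs[2]

    def test_matrix_plant_matches_oracle(self):
        # damped oscillator with time-varying damping (non-commuting A(t))
        A = lambda t: np.array([[0.0, 1.0], [-9.0, -0.4 * (1.0 + 0.5 * math.sin(t))]])
        B = lambda t: np.array([[0.0], [1.0]])
        sys2 = LTVSystem(state_dim=2, input_dim=1, A=A, B=B, x0=[1.0, 0.0])
        x = solve_state(sys2, u_sin, 1.0, dt=1e-3)
        f = lambda t, v: A(t) @ v + B(t) @ np.atleast_1d(u_sin(t))
        oracle = rk4_solve(f, sys2.x0, 0.0, 1.0, 20000)
        assert np.allclose(x, oracle, rtol=1e-5, atol=1e-8)

    def test_semigroup_consistency(self, ltv_scalar):
        # propagating x(s) forward through the flow plus the input integral
        # reproduces the direct solution at t
        G = transition_operator(ltv_scalar)
        s, t = 0.6, 1.4
        x_s = solve_state(ltv_scalar, u_sin, s, dt=1e-4, transition=G)
        grid = np.linspace(s, t, 8001)
        z = G.log_scale_array(grid)
        integrand = np.exp(z[-1] - z) * np.array(
            [ltv_scalar.B_mat(v)[0, 0] * u_sin(v) for v in grid]
        )
        x_t = G.propagator(s, t)[0, 0] * x_s[0] + np.trapezoid(integrand, grid)
        direct = solve_state(ltv_scalar, u_sin, t, dt=1e-4, transition=G)
        assert x_t == pytest.approx(direct[0], rel=1e-6)

    def test_undefined_control_raises_domain_error(self):
        sys1 = LTVSystem.scalar(a=-1.0, b=1.0)

        def u_partial(t):
            if t > 0.5:
                raise ValueError("not defined here")
            return 1.0

        with pytest.raises(DomainError):
            solve_state(sys1, u_partial, 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            solve_state(LTVSystem.scalar(a=-1.0, b=1.0), lambda t: 0.0, -0.5)


class TestDelayedState:
    def test_zero_lag_identical_to_current_state(self, ltv_scalar):
        assert delayed_state(ltv_scalar, u_sin, 1.0, 0.0) == pytest.approx(
            solve_state(ltv_scalar, u_sin, 1.0)
        )

    def test_full_lag_returns_initial_state(self, ltv_scalar):
        assert delayed_state(ltv_scalar, u_sin, 1.0, 1.0)[0] == ltv_scalar.x0[0]

    def test_small_lag_consistent_with_direct_solution(self):
        sysh = LTVSystem.scalar(a=-5.0, b=5.0, x0=0.2)  # oculomotor constants
        lagged = delayed_state(sysh, u_sin, 1.0, 0.01)
        direct = solve_state(sysh, u_sin, 0.99)
        assert abs(lagged[0] - direct[0]) <= 1e-9

    @pytest.mark.parametrize("lag", [-0.1, 1.2])
    def test_lag_outside_domain_rejected(self, ltv_scalar, lag):
        with pytest.raises(DomainError):
            delayed_state(ltv_scalar, u_sin, 1.0, lag)


class TestLTVSystemValidation:
    def test_dimensions_must_be_positive(self):
        with pytest.raises(ShapeError):
            LTVSystem(state_dim=0, input_dim=1, A=lambda t: np.eye(0), B=lambda t: np.zeros((0, 1)))

    def test_x0_shape_checked(self):
        with pytest.raises(ShapeError):
            LTVSystem(
                state_dim=2, input_dim=1,
                A=lambda t: np.eye(2), B=lambda t: np.zeros((2, 1)), x0=[1.0],
            )

    def test_mis_shaped_dynamics_rejected(self):
        with pytest.raises(PlantEvaluationError):
            LTVSystem(
                state_dim=2, input_dim=1,
                A=lambda t: np.eye(3), B=lambda t: np.zeros((2, 1)), x0=[0.0, 0.0],
            )
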