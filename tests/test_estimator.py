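import math

import numpy as np
import pytest

from _oracles import rk4_solve
from delayloop import (
    DelayEstimate,
    DomainError,
    HistoryBuffer,
    LTVSystem,
    ShapeError,
    delay_gradient,
    delay_gradient_full_history,
    estimation_error,
    hvor_delay_update,
    solve_state,
    transition_operator,
    update_delay_estimate,
)

C, RHO = 5.0, 0.2  # oculomotor decay kappa/rho and elasticity


def u_sin(t):
    return 1.5 * math.sin(2.0 * math.pi * t + 0.3)


def _filled_buffers(system, u, t_end, dt=1e-4, window=0.06):
    """State and command buffers holding the true trajectory over a window.

    The trajectory enters the window via the variation-of-constants solution
    and is continued across it by fine-step Runge-Kutta.
    """
    xbuf, ubuf = HistoryBuffer(window), HistoryBuffer(window)
    G = transition_operator(system)
    t0 = max(0.0, t_end - window)
    x = float(solve_state(system, u, t0, dt=dt, transition=G)[0])
    f = lambda s, v: system.A_mat(s)[0, 0] * v + system.B_mat(s)[0, 0] * u(s)
    xbuf.record(t0, x)
    ubuf.record(t0, u(t0))
    for k in range(int(round((t_end - t0) / dt))):
        s = t0 + k * dt
        k1 = f(s, x)
        k2 = f(s + 0.5 * dt, x + 0.5 * dt * k1)
        k3 = f(s + 0.5 * dt, x + 0.5 * dt * k2)
        k4 = f(s + dt, x + dt * k3)
        x += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        s_next = t0 + (k + 1) * dt
        xbuf.record(s_next, x)
        ubuf.record(s_next, u(s_next))
    return xbuf, ubuf, G


class TestEstimationError:
    def test_identical_inputs_give_zero(self):
        assert estimation_error(2.0, 2.0) == 0.0

    def test_plain_subtraction(self):
        assert estimation_error(2.0, 1.5) == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            estimation_error([1.0, 2.0], [1.0])

    def test_matches_delayed_solution_discrepancy(self):
        # zeta for a 10 ms true lag against a 5 ms hypothesis equals
        # x(t-0.010) - x(t-0.005) computed by the independent ODE oracle
        sysh = LTVSystem.scalar(a=-C, b=1.0 / RHO, x0=0.4)
        f = lambda s, v: -C * v + np.atleast_1d(u_sin(s)) / RHO
        t = 1.0
        xa = rk4_solve(f, sysh.x0, 0.0, t - 0.010, 10000)[0]
        xb = rk4_solve(f, sysh.x0, 0.0, t - 0.005, 10000)[0]
        za = solve_state(sysh, u_sin, t - 0.010)[0]
        zb = solve_state(sysh, u_sin, t - 0.005)[0]
        assert estimation_error(za, zb)[0] == pytest.approx(xa - xb, abs=1e-8)


class TestDelayGradient:
    def test_flat_equilibrium_carries_no_delay_information(self):
        sys0 = LTVSystem.scalar(a=0.0, b=1.0, x0=1.0)
        xbuf, ubuf, _ = _filled_buffers(sys0, lambda t: 0.0, 0.1)
        assert delay_gradient(sys0, ubuf, xbuf, 0.02, 0.1)[0] == 0.0

    def test_gradient_sign_follows_local_slope(self):
        # for a rising trajectory, increasing tau_hat looks further back and
        # lowers the reconstructed state, so d zeta/d tau_hat = +x_dot > 0
        sysr = LTVSystem.scalar(a=0.0, b=1.0, x0=0.0)
        xbuf, ubuf, _ = _filled_buffers(sysr, lambda t: 2.0, 0.1)  # ramp x = 2t
        g = delay_gradient(sysr, ubuf, xbuf, 0.02, 0.1)[0]
        assert g == pytest.approx(2.0, rel=1e-9)

    def test_buffered_route_agrees_with_full_history_route(self):
        sysh = LTVSystem.scalar(a=-C, b=1.0 / RHO, x0=0.4)
        xbuf, ubuf, G = _filled_buffers(sysh, u_sin, 1.0)
        for th in (0.004, 0.017, 0.041):
            g_buf = delay_gradient(sysh, ubuf, xbuf, th, 1.0)[0]
            g_full = delay_gradient_full_history(sysh, G, u_sin, th, 1.0)[0]
            assert g_buf == pytest.approx(g_full, rel=1e-5, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_central_finite_difference(self, seed):
        rng = np.random.default_rng(seed)
        a, b, x0 = rng.uniform(-8, -0.5), rng.uniform(0.5, 3), rng.uniform(-1, 1)
        amp, fr, ph = rng.uniform(0.5, 3), rng.uniform(0.3, 2), rng.uniform(0, 6)
        uu = lambda s: amp * math.sin(2 * math.pi * fr * s + ph)
        sysr = LTVSystem.scalar(a=a, b=b, x0=x0)
        G = transition_operator(sysr)
        t, th, h = 1.0, float(rng.uniform(0.002, 0.045)), 1e-5
        g = delay_gradient_full_history(sysr, G, uu, th, t, dt=2e-4)[0]
        # zeta(tau_hat) = x(t - tau) - x(t - tau_hat); only the second term moves
        zp = -solve_state(sysr, uu, t - (th + h), dt=2e-4, transition=G)[0]
        zm = -solve_state(sysr, uu, t - (th - h), dt=2e-4, transition=G)[0]
        fd = (zp - zm) / (2.0 * h)
        assert abs(g - fd) / max(abs(fd), 1e-12) <= 1e-3


class TestUpdateDelayEstimate:
    def test_zero_error_freezes_the_estimate(self):
        est = DelayEstimate(tau_hat=0.02, eta=1.0, tau_max=0.05)
        out = update_delay_estimate(est, 0.0, 3.0, 1e-4)
        assert out.tau_hat == 0.02

    def test_clamped_at_lower_bound(self):
        est = DelayEstimate(tau_hat=0.0, eta=1.0, tau_max=0.05)
        # zeta * gradient > 0 proposes a negative excursion; clamp holds at 0
        out = update_delay_estimate(est, 1.0, 5.0, 1e-2)
        assert out.tau_hat == 0.0

    def test_clamped_at_upper_bound(self):
        est = DelayEstimate(tau_hat=0.05, eta=1.0, tau_max=0.05)
        out = update_delay_estimate(est, 1.0, -5.0, 10.0)
        assert out.tau_hat == 0.05

    def test_slew_limit_caps_the_descent_rate(self):
        est = DelayEstimate(tau_hat=0.02, eta=1e6, tau_max=0.05, max_rate=0.5)
        out = update_delay_estimate(est, 1.0, 1.0, 1e-3)
        assert est.tau_hat - out.tau_hat == pytest.approx(0.5 * 1e-3)

    def test_vector_error_uses_inner_product(self):
        est = DelayEstimate(tau_hat=0.02, eta=1.0, tau_max=0.05)
        out = update_delay_estimate(est, [1.0, 2.0], [3.0, -1.0], 1e-3)
        assert est.tau_hat - out.tau_hat == pytest.approx((3.0 - 2.0) * 1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            DelayEstimate(tau_hat=0.06, eta=1.0, tau_max=0.05)
        with pytest.raises(DomainError):
            DelayEstimate(tau_hat=0.01, eta=-1.0, tau_max=0.05)


class TestHvorDelayUpdate:
    def test_quiescent_plant_gives_no_update(self):
        sysh = LTVSystem.scalar(a=-C, b=1.0 / RHO, x0=0.0)
        xbuf, ubuf, _ = _filled_buffers(sysh, lambda t: 0.0, 0.1)
        est = DelayEstimate(tau_hat=0.02, eta=1.0, tau_max=0.05)
        out = hvor_delay_update(est, 1.0, RHO, measured=0.0, u_buffer=ubuf,
                                x_buffer=xbuf, t=0.1, dt=1e-4)
        assert out.tau_hat == est.tau_hat

    def test_specialisation_equals_general_path(self):
        sysh = LTVSystem.scalar(a=-C, b=1.0 / RHO, x0=0.4)
        xbuf, ubuf, _ = _filled_buffers(sysh, u_sin, 1.0)
        measured = float(xbuf.sample(1.0 - 0.010))  # sensed x(t - tau)
        est = DelayEstimate(tau_hat=0.025, eta=0.05, tau_max=0.05)
        out_special = hvor_delay_update(est, 1.0, RHO, measured, ubuf, xbuf, 1.0, 1e-4)
        zeta = estimation_error(measured, xbuf.sample(1.0 - est.tau_hat))
        grad = delay_gradient(sysh, ubuf, xbuf, est.tau_hat, 1.0)
        out_general = update_delay_estimate(est, zeta, grad, 1e-4)
        assert abs(out_special.tau_hat - out_general.tau_hat) <= 1e-6


class TestConvergence:
    def test_constant_delay_estimate_settles_on_truth(self, compensated_run):
        # |tau_hat - tau| shrinks through the transient and stays small
        res = compensated_run
        err = np.abs(res.eps)
        checkpoints = [err[np.searchsorted(res.t, s)] for s in (0.05, 0.3, 1.0, 4.0)]
        assert checkpoints[0] > checkpoints[1] >= checkpoints[2] >= checkpoints[3]
        assert err[-1] <= 1e-6

    def test_estimate_never_leaves_admissible_interval(self, compensated_run):
        assert compensated_run.tau_hat.min() >= 0.0
        assert compensated_run.tau_hat.max() <= 0.05
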