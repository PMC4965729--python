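# Methods

## Model and assumptions

The simulator studies feedback control when the controller's only view of
the plant state is a delayed measurement `x(t − τ(t))` with `τ` unknown and
bounded, `0 ≤ τ(t) ≤ τ_max`. Three assumptions define the architecture:

1. the controller carries an exact internal forward model of the plant
   (`A`, `B` and the issued commands `u` are known to it; state and command
   sensing is noise-free in the default conditions);
2. signals are remembered only over the sliding window `[t − τ_max, t]`,
   so delays beyond `τ_max` make feedback impossible (the loop then
   degrades to open-loop, which the engine flags and handles by zeroing
   the command);
3. there is no global clock: the controller never reads `τ` — it maintains
   its own estimate `τ̂` and treats the measurement as being `τ̂` old, the
   only self-consistent interpretation available to it.

Under these assumptions the delay estimate descends the squared
discrepancy `ζ = x(t−τ) − x_model(t−τ̂)`:

    dτ̂/dt = −η ζ ∂ζ/∂τ̂,   ∂ζ/∂τ̂ = A(t−τ̂)x(t−τ̂) + B(t−τ̂)u(t−τ̂),

clamped to `[0, τ_max]`. The gradient expression is the collapsed form of
differentiating the delayed variation-of-constants solution with respect to
the hypothesised lag; `delay_gradient_full_history` evaluates the expanded
operator form and the test-suite pins both against central finite
differences. `ζ` vanishes identically at `τ̂ = τ`, making the true delay a
fixed point regardless of what the controller is doing — estimation and
control are decoupled in the exact-model setting.

The predictor propagates the measurement to the present along the plant
flow and adds the effect of the commands issued during the lag. When
`τ̂ = τ` the prediction equals the true current state, so a controller
designed on the delay-free plant recovers its nominal behaviour.

## The hVOR instantiation

Eye position relative to the head follows `ẋ = −(κ/ρ)x + u/ρ`. Parameters
and defaults (all configurable through `make_scenario` overrides):

| parameter | default | meaning |
| --- | --- | --- |
| κ, ρ | 1.0, 0.2 | viscosity, elasticity; time constant ρ/κ = 200 ms, a standard oculomotor value. Only the ratio matters to the closed loop. |
| head motion | 40 °/s, 1 Hz sinusoid | periodic horizontal head velocity; amplitude/frequency are conventions, the loop properties are robust to them |
| τ profiles | 10 ms constant; 10 + 4·sin(2π·0.2 t) ms | the constant-delay and drifting-delay experiments |
| τ_max | 50 ms | memory window; covers the 10 ms delay with margin |
| τ̂(0) | τ_max/2 = 25 ms | unbiased within the admissible interval (0 in the zero-delay baseline, where the discrepancy is then identically zero) |
| K_D | 40 | derivative gain, designed on the zero-delay plant: loop gain K_D/ρ = 200 gives steady-state slip ≈ 0.6 % of peak head speed |
| derivative filter | 40 ms | first-order low-pass on the derivative term (below) |
| η | 0.5 | estimator learning rate |
| estimator slew limit | 0.5 s/s | rate cap on dτ̂/dt (below) |
| u_max | 500 | motor-command saturation; never binds in compensated runs (commands stay below ~15) but bounds the uncompensated oscillation |
| dt | 1e-4 s | engine step: 100 grid points across the 10 ms delay |

The sensed quantity is the plant state `x` (eye position); velocities and
the retinal slip `y = ẋ + ḣ` are derived outputs for reporting.

## Numerical choices

**Engine order of operations** (fixed, since the continuous architecture
does not dictate it): per step — sense from the state history at `t − τ`
(linear interpolation; `x₀` held while `t < τ`), update `τ̂`, predict,
form `ê = r − x̂`, compute `u`, saturate, advance the plant one RK4 step
with `u` held constant, record buffers. The estimator update therefore uses
the previous step's commands; the prediction uses commands up to the
current step.

**Exact-model shortcut.** Because the forward model equals the plant, the
engine reads `x_model(t − τ̂)` from the simulated state history instead of
re-integrating the variation-of-constants reconstruction every step. The
module layer (`delayed_state`, `predict_state`) provides the honest
reconstructions and the tests pin their equivalence. The shortcut is what
makes the no-delay degeneracy exact: with `τ ≡ 0` and `τ̂(0) = 0` the
discrepancy is bitwise zero and the compensated loop reproduces the plain
feedback loop identically.

**Predictor integral.** Maintained as the convolution state
`I(t) = ∫₀ᵗ e^{−c(t−s)} u(s)/ρ ds` via its exact zero-order-hold
recurrence and buffered over the window, so no large exponentials appear at
any horizon; `x̂ = e^{−cτ̂}(x_meas − I(t−τ̂)) + I(t)`.

**Filtered derivative.** The continuous derivative law is stable at
arbitrary gain because the algebraic loop through `ẋ` is implicit.  Its
explicit discrete realisation (backward difference on `ê`) is
unconditionally unstable once `K_D/ρ > 1` — the characteristic root product
is `−K_D/ρ` at any step size — so the derivative term carries a standard
first-order low-pass (40 ms in the hVOR scenarios, per-step gain
`(K_D/ρ)·dt/(T_f+dt) ≈ 0.5`). The filter costs a few degrees of phase at
1 Hz and leaves the slip well under the 1 % design goal. An unfiltered
backward difference remains available (`derivative_filter_tau = 0`).

**Slew-limited estimation.** While `|τ̂ − τ|` is large the high-gain loop
is transiently unstable (its delay margin is ~1 ms against initial
mismatches of up to 25 ms), so estimation and instability race. The
estimator therefore runs fast (η = 0.5) with `dτ̂/dt` capped at 0.5 s/s:
away from the optimum it behaves as sign-gradient descent at a fixed,
amplitude-independent speed — converging from the worst-case 25 ms
mismatch in ~50 ms of motion, before oscillation can build — and near the
optimum the cap is inactive and the plain gradient law applies. The cap
also keeps the explicit Euler update stable when transient amplitudes make
`η|ζ ∂ζ/∂τ̂|` momentarily huge. Without it, convergence depends on a race
whose outcome flips with rounding-level perturbations.

**Degenerate inputs and ties.** `τ̂ = 0` is an exact measurement
passthrough in both predictor routes; empty quadrature segments integrate
to exactly zero; buffer eviction keeps the window-edge sample; buffers
carry a two-step guard band so window-edge queries survive floating-point
rounding of `t − τ_max` against grid timestamps.

## What the generated conditions do and do not show

All inputs are synthetic: sinusoidal head motion, constant/sinusoidal/step
delay profiles, and randomized stable scalar plants
(`a ∈ [−10, −0.1] s⁻¹`) for property tests. They emulate periodic
vestibular stimulation and the physiological delay range (1–40 ms), which
is what the closed-loop claims are about. They do not emulate: sensor or
motor noise (a seeded additive-noise hook exists but the default conditions
are noise-free — see limitations), model mismatch between plant and
internal model, saccadic corrections, or nonlinear muscle mechanics.
Passing tests therefore demonstrate the mechanism — delay estimation,
prediction, and stabilisation under exact modelling — not robustness of a
physiological eye plant.

## Problem sizes

The closed-loop experiments run 5 s at `dt = 1e-4` s (50 000 steps,
roughly a second of wall time each); the gradient-correctness check uses
100 randomized plants against central finite differences (step 1e-5 s);
predictor/oracle equivalences use fixed-step RK4 oracles with 4 000 steps
over the lag window.

## Known limitations

- The engine's closed loop is scalar-state (every scenario is); the
  plant/estimator/predictor modules are dimension-generic and tested as
  such, including non-commuting matrix plants.
- Per-sample white sensory noise is amplified by the high-gain derivative
  loop (gain ~`K_D/T_f` on the sensed signal); runs with `noise_std` well
  above interpolation error need gentler gains or heavier filtering. The
  noise hook is exercised for determinism, not performance.
- With `u(0) ≠ 0` plants the estimator's lagged-command lookup treats
  pre-start commands as zero, consistent with the quiescent-start
  assumption.
- The static feedback gain `K` is user-supplied; no optimal-gain synthesis
  is performed.
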