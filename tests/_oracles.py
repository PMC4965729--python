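"""Independent numerical oracles used by the test-suite.

Deliberately minimal and separate from the package: a plain fixed-step
4th-order Runge-Kutta integrator used to cross-check the package's
variation-of-constants solutions and predictors.
"""

import numpy as np


def rk4_solve(f, x0, t0, t1, n):
    """Integrate ``dx/dt = f(t, x)`` from ``t0`` to ``t1`` in ``n`` fixed steps."""
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    h = (t1 - t0) / n
    t = t0
    for _ in range(n):
        k1 = f(t, x)
        k2 = f(t + 0.5 * h, x + 0.5 * h * k1)
        k3 = f(t + 0.5 * h, x + 0.5 * h * k2)
        k4 = f(t + h, x + h * k3)
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += h
    return x
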