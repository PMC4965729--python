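"""Programmatic generators of signals and randomized plants for testing.

The simulator takes no external data: head-motion profiles, delay profiles
and the randomized scalar plants used by property tests are all generated
here, fully determined by ``(family, parameters, seed)``.  Random plant
coefficients are restricted to stable decay so closed-form oracles stay
well-conditioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .errors import ConfigError
from .plant import LTVSystem

__all__ = ["FixtureSpec", "generate", "FAMILIES"]

FAMILIES = ("sinusoid", "step", "chirp", "random_lti", "random_ltv")

# stable scalar decay range for randomized plants (1/s)
_A_RANGE = (-10.0, -0.1)
_B_RANGE = (0.5, 5.0)
_X0_RANGE = (-2.0, 2.0)


@dataclass(frozen=True)
class FixtureSpec:
    """A named signal/plant family plus its parameters.

    Families
    --------
    sinusoid(amplitude, frequency)      -> callable t -> A sin(2 pi f t)
    step(height, at, before=0.0)        -> callable, ``before`` until ``at``
    chirp(amplitude, f0, rate)          -> callable, linearly swept sinusoid
    random_lti(seed)                    -> stable scalar LTVSystem, constant a, b
    random_ltv(seed, mod_frequency)     -> stable scalar LTVSystem, sinusoidal a(t), b(t)
    """

    family: str
    parameters: dict = field(default_factory=dict)
    horizon: float = 5.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(
                f"unknown fixture family {self.family!r}; valid: {', '.join(FAMILIES)}"
            )


def generate(spec: FixtureSpec) -> "Callable[[float], float] | LTVSystem":
    """Materialise a fixture: a signal callable or a randomized plant."""
    p: dict[str, Any] = dict(spec.parameters)
    if spec.family == "sinusoid":
        amp = float(p.pop("amplitude", 1.0))
        freq = float(p.pop("frequency", 1.0))
        _reject_extra(p)
        w = 2.0 * math.pi * freq
        return lambda t: amp * math.sin(w * t)
    if spec.family == "step":
        height = float(p.pop("height", 1.0))
        at = float(p.pop("at", 1.0))
        before = float(p.pop("before", 0.0))
        _reject_extra(p)
        return lambda t: before if t < at else height
    if spec.family == "chirp":
        amp = float(p.pop("amplitude", 1.0))
        f0 = float(p.pop("f0", 0.5))
        rate = float(p.pop("rate", 0.5))  # Hz per second
        _reject_extra(p)
        return lambda t: amp * math.sin(2.0 * math.pi * (f0 * t + 0.5 * rate * t * t))
    if spec.family == "random_lti":
        rng = np.random.default_rng(int(p.pop("seed", 0)))
        _reject_extra(p)
        a = float(rng.uniform(*_A_RANGE))
        b = float(rng.uniform(*_B_RANGE))
        x0 = float(rng.uniform(*_X0_RANGE))
        return LTVSystem.scalar(a=a, b=b, x0=x0)
    if spec.family == "random_ltv":
        rng = np.random.default_rng(int(p.pop("seed", 0)))
        mod_freq = float(p.pop("mod_frequency", 0.5))
        _reject_extra(p)
        # a(t) = a0 + a1 sin(...) stays within the stable range by construction
        a0 = float(rng.uniform(-8.0, -2.0))
        a1 = float(rng.uniform(0.0, min(abs(a0) - 0.5, 3.0)))
        b0 = float(rng.uniform(*_B_RANGE))
        b1 = float(rng.uniform(0.0, 0.5 * b0))
        x0 = float(rng.uniform(*_X0_RANGE))
        w = 2.0 * math.pi * mod_freq
        return LTVSystem.scalar(
            a=lambda t: a0 + a1 * math.sin(w * t),
            b=lambda t: b0 + b1 * math.cos(w * t),
            x0=x0,
        )
    raise ConfigError(f"unknown fixture family {spec.family!r}")  # pragma: no cover


def _reject_extra(p: dict) -> None:
    if p:
        raise ConfigError(f"unknown fixture parameters: {sorted(p)}")
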