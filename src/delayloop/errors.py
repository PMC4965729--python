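"""Exception types shared across the package."""


class DelayLoopError(Exception):
    """Base class for all package-specific errors."""


class PlantEvaluationError(DelayLoopError):
    """A(t) or B(t) returned a non-finite or mis-shaped matrix at some t."""


class DomainError(DelayLoopError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class OrderingError(DelayLoopError, ValueError):
    """A timestamp was not strictly increasing."""


class OutOfWindowError(DelayLoopError, ValueError):
    """A query time fell outside the bounded memory window [t - tau_max, t].

    In the closed loop this is the regime where the hypothesised delay
    exceeds the buffer capacity and the controller must fall back to
    open-loop behaviour; callers are expected to handle it.
    """


class ShapeError(DelayLoopError, ValueError):
    """Vector/matrix operands have incompatible shapes."""


class ConfigError(DelayLoopError, ValueError):
    """A simulation or scenario configuration is invalid."""
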