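"""Exception hierarchy.

All failures that correspond to a scientific infeasibility (rather than a
programming error) raise a named subclass of :class:`StateBridgeError`, so
callers can distinguish "this transition is impossible under the baseline
dynamics" from a bug.
"""


class StateBridgeError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(StateBridgeError):
    """Shapes of distributions / kernels do not agree."""


class SupportViolationError(StateBridgeError):
    """P places mass where Q has none: KL(P || Q) is undefined (infinite)."""


class InfeasibleMarginalError(StateBridgeError):
    """A requested marginal puts mass on states unreachable under Q.

    Carries ``states``: the offending state indices (0-based).
    """

    def __init__(self, message: str, states=()):
        super().__init__(message)
        self.states = tuple(states)


class ConvergenceError(StateBridgeError):
    """Sinkhorn failed to reach tolerance within the iteration budget.

    Carries ``residual``: the last marginal residual, and ``iterations``.
    """

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class UnobservedStateError(StateBridgeError):
    """A state never occurs as a transition source; its kernel row is undefined."""


class DegenerateVarianceError(StateBridgeError):
    """Pooled variance is zero; the t statistic is undefined."""


class NonErgodicKernelError(StateBridgeError):
    """Stationary start requested for a kernel without a unique stationary law."""


class MalformedFileError(StateBridgeError):
    """Input file violates the expected format. Carries ``line`` when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
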