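"""Exception hierarchy shared across the package."""


class NetfluctError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NetfluctError, ValueError):
    """An input violates a documented precondition."""


class NumericalError(NetfluctError, ArithmeticError):
    """A numerical routine produced non-finite or unphysical state."""


class ConvergenceError(NetfluctError, RuntimeError):
    """An iterative routine exhausted its attempt budget.

    Attributes
    ----------
    best : float or None
        Best score achieved before giving up (e.g. the highest
        strength-sequence correlation seen while rewiring).
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class UndefinedCorrelationError(NetfluctError, ValueError):
    """A correlation is undefined because a series is constant."""


class InsufficientDataError(NetfluctError, ValueError):
    """Too few samples/observations for the requested statistic."""
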