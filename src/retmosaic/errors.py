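"""Exception hierarchy.

All package-specific errors derive from :class:`RetmosaicError` so callers can
catch everything with one clause; most also subclass the matching builtin.
"""


class RetmosaicError(Exception):
    """Base class for all retmosaic errors."""


class InvalidSpecError(RetmosaicError, ValueError):
    """A generator or analysis specification violates its invariants."""


class SimulationFailureError(RetmosaicError, RuntimeError):
    """A stochastic simulation could not satisfy its contract.

    Carries ``achieved_n``: how many points were placed before giving up.
    """

    def __init__(self, message: str, achieved_n: int | None = None):
        super().__init__(message)
        self.achieved_n = achieved_n


class InsufficientPointsError(RetmosaicError, ValueError):
    """Too few points (or values) for the requested statistic."""


class DegenerateGeometryError(RetmosaicError, ValueError):
    """Collinear / zero-area input where a 2-D geometry is required."""


class UndefinedStatisticError(RetmosaicError, ValueError):
    """The statistic is mathematically undefined for this input (e.g. zero SD)."""


class LoadError(RetmosaicError, ValueError):
    """A file failed validation on read; the message names the offending rows."""


class UnbalancedDesignError(RetmosaicError, ValueError):
    """A factorial design has empty cells; the message names them."""
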