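"""Exception hierarchy for the geostoich package.

All errors derive from :class:`GeostoichError` so callers can catch the
package's failures with one clause; the leaves also subclass the closest
built-in (``ValueError`` for bad arguments) so generic handling still works.
"""


class GeostoichError(Exception):
    """Base class for all geostoich errors."""


class InvalidArgumentError(GeostoichError, ValueError):
    """An argument violates a documented precondition."""


class InvalidParameterError(InvalidArgumentError):
    """A model parameter is outside its admissible range."""


class InfeasibleParametersError(GeostoichError, ValueError):
    """The budget equations have no nonnegative solution for this parameter set.

    Raised in reverse mode when the intake system is singular (specific
    dynamic action consumes more carbon than absorption can supply) or when
    the unique solution has a negative intake component.
    """


class ParseError(GeostoichError, ValueError):
    """A trial-table cell could not be parsed; message names row and column."""


class SchemaError(GeostoichError, ValueError):
    """A trial table violates the documented schema (header, duplicates)."""


class NoSolutionError(GeostoichError, RuntimeError):
    """Calibration found no feasible point anywhere on the search grid."""


class UndefinedStatisticError(GeostoichError, ValueError):
    """A requested statistic is undefined for the given data (zero variance)."""
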