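"""Exception hierarchy shared across the package."""


class PhenoceilingError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PhenoceilingError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(PhenoceilingError):
    """Too few usable observations for the requested fit."""


class DegenerateDesignError(PhenoceilingError):
    """Design matrix is singular (e.g. constant predictor or response)."""


class NoIntersectionError(PhenoceilingError):
    """Two scaling lines are parallel and never intersect."""


class UnsolvableError(PhenoceilingError):
    """The energy-equivalence equation has no solution (zero slope)."""


class ValidationError(PhenoceilingError, ValueError):
    """Input table rows violate schema invariants."""


class NewickParseError(PhenoceilingError, ValueError):
    """Malformed Newick input."""
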