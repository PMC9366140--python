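"""Exception hierarchy for the adslow package.

All package-specific failures derive from :class:`AdslowError`, so callers
(and the command-line layer, which maps them to exit code 2) can catch one
type. I/O problems are left to the builtin ``OSError`` family.
"""


class AdslowError(Exception):
    """Base class for all adslow-specific errors."""


class FormatError(AdslowError):
    """A tabular input file does not conform to the expected dialect."""


class ValidationError(AdslowError):
    """Data violates a structural invariant (ordering, sign, containment)."""


class ParameterError(AdslowError):
    """A parameter is outside its admissible domain."""


class EmptyInputError(AdslowError):
    """An operation received an empty series where at least one point is required."""


class DegenerateInputError(AdslowError):
    """An operation would leave no usable data (e.g. every point screened out)."""


class CoverageError(AdslowError):
    """A latency point falls outside every protocol segment."""


class PlacementError(AdslowError):
    """A stimulus (extra train) cannot be placed without colliding with another."""
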