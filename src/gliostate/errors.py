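"""Exception hierarchy.

Every error raised by the package derives from :class:`GliostateError`, so
callers can catch one type at a pipeline boundary while still distinguishing
stages by subclass.
"""


class GliostateError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(GliostateError, ValueError):
    """A simulation design violates its invariants."""


class InvalidParameterError(GliostateError, ValueError):
    """A parameter is outside its documented range."""


class InvalidInputError(GliostateError, ValueError):
    """Numeric input violates a precondition (e.g. p-value outside [0, 1])."""


class NormalizationError(GliostateError):
    """Housekeeping normalization cannot proceed (missing gene, zero count)."""


class ContrastError(GliostateError):
    """A differential-expression contrast names an unknown condition."""


class ScalingError(GliostateError):
    """Sum-of-squares scaling undefined (all-zero fold-change vector)."""


class ClusteringError(GliostateError):
    """Clustering cannot proceed (missing values, too few items)."""


class AlignmentError(GliostateError):
    """Orthology alignment left no usable gene pairs."""


class UndefinedStatisticError(GliostateError):
    """A statistic (correlation, lag) is undefined for the given input."""


class ParseError(GliostateError):
    """A TSV input violates its format contract."""
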