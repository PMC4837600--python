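"""Exception hierarchy for growthfit.

All errors raised by the library derive from :class:`GrowthfitError` so
callers can catch everything with one clause; the subclasses distinguish
bad arguments from data that is merely unfit for analysis.
"""


class GrowthfitError(Exception):
    """Base class for all growthfit errors."""


class InvalidInputError(GrowthfitError, ValueError):
    """Malformed or non-finite input (wrong shapes, NaN/inf, unsorted times)."""


class InvalidIntervalError(InvalidInputError):
    """An integration or AUC window with t_end < t_start."""


class NonPositiveRateError(GrowthfitError, ValueError):
    """Doubling time requested for a growth rate r <= 0."""


class DegenerateSampleError(GrowthfitError, ValueError):
    """A sample carrying no usable signal (e.g. all-zero readings)."""


class InsufficientDataError(GrowthfitError, ValueError):
    """Fewer data points than the operation requires."""


class PlateParseError(GrowthfitError, ValueError):
    """A plate table file that cannot be parsed; message names row/column."""
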