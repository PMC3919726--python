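"""Exception hierarchy.

Everything raised by this package derives from :class:`AdheritError`, so
pipeline drivers can distinguish data problems from programming errors.
"""


class AdheritError(Exception):
    """Base class for all package errors."""


class SchemaError(AdheritError):
    """An input table is missing a required column or has the wrong shape."""


class ValidationError(AdheritError):
    """A row or value violates a domain invariant (bad well label, negative
    RFU, duplicated sample, ...). Carries enough context to locate the row."""


class InsufficientDataError(AdheritError):
    """Too few replicates / pairs / curve points for the statistic to be
    defined."""


class DegenerateDataError(AdheritError):
    """The statistic is undefined on this data (zero variance, equal control
    means, value on a curve asymptote)."""


class CurveFitError(AdheritError):
    """4PL least-squares fit failed to converge.

    ``best_params`` holds the last iterate when the optimizer produced one.
    """

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class OutOfRangeError(AdheritError):
    """A fluorescence value lies outside the invertible range of the fitted
    standard curve; no extrapolation is performed."""


class ConfigError(AdheritError):
    """A run or generator configuration violates its invariants."""
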