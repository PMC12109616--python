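"""Exception hierarchy shared across the package."""


class BimetaError(Exception):
    """Base class for all package errors."""


class FormatError(BimetaError):
    """Malformed input file (bad header, duplicate ids, non-numeric cells...)."""


class DomainError(BimetaError):
    """Input values outside the mathematical domain of an operation."""


class DegenerateInputError(BimetaError):
    """Input with no usable variation (constant vector, zero-variance gene...)."""


class DegenerateFitError(BimetaError):
    """A fitted model is too degenerate for the requested downstream use."""


class NotEstimableError(BimetaError):
    """A model cannot be estimated from the data provided (e.g. zero events)."""


class RankDeficiencyError(BimetaError):
    """Design matrix is rank deficient (collinear or duplicated predictors)."""
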