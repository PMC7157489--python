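"""Exception types shared across the pipeline."""


class InvalidInputError(ValueError):
    """An input violates a precondition (shape, range, emptiness)."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given plane (e.g. spectral
    slope of a constant field, where every non-DC amplitude is zero)."""


class InsufficientDataError(ValueError):
    """Too few records to run an analysis (correlation, PLSR, ANOVA)."""


class DegeneratePredictorError(ValueError):
    """A predictor column has zero variance and cannot be z-scored."""
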