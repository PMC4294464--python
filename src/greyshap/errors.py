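"""Exception hierarchy for greyshap."""


class GreyShapError(Exception):
    """Base class for all greyshap errors."""


class ValidationError(GreyShapError, ValueError):
    """Input data violates a domain invariant (lengths, positivity, years)."""


class SchemaError(GreyShapError, ValueError):
    """A file or frame does not match the expected tabular schema."""


class AlignmentError(GreyShapError, ValueError):
    """Two year-indexed objects do not cover the same years."""


class DegenerateFitError(GreyShapError, ArithmeticError):
    """The least-squares system is singular or rank deficient."""


class EvaluationError(GreyShapError, ArithmeticError):
    """A model formula cannot be evaluated (vanishing denominator etc.)."""
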