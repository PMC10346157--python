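"""Exception hierarchy shared across the package.

All validation failures are errors, never warnings: a soft sensor that
silently coerces bad plant data produces confidently wrong predictions.
"""


class FermsenseError(Exception):
    """Base class for all package errors."""


class ValidationError(FermsenseError, ValueError):
    """An input violates a documented invariant (value out of range, NaN, ...)."""


class ShapeError(ValidationError):
    """Array dimensions are inconsistent with the operation's contract."""


class SchemaError(ValidationError):
    """A data file does not conform to the batch file schema."""


class NumericalError(FermsenseError, RuntimeError):
    """A linear-algebra step failed or was refused (ill-conditioning, non-PD)."""


class PipelineError(FermsenseError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
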