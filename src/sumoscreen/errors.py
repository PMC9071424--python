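"""Exception hierarchy shared across the pipeline stages.

Exit-code mapping used by the CLI: :class:`ValidationError` -> 2,
:class:`DegenerateDataError` -> 3.
"""


class SumoscreenError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(SumoscreenError):
    """Bad input: malformed file, missing column, invalid parameter."""


class FormatError(ValidationError):
    """A structured input file does not follow its expected dialect."""


class DegenerateDataError(SumoscreenError):
    """Input is well-formed but carries no usable signal (zero variance,
    empty scan, all-flagged spots, ...)."""
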