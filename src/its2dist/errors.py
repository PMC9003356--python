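"""Exception hierarchy for the its2dist package."""


class Its2DistError(Exception):
    """Base class for all package errors."""


class ViennaFormatError(Its2DistError):
    """Malformed Vienna (header/sequence/dot-bracket) record."""


class StructureError(Its2DistError):
    """Unbalanced or otherwise invalid dot-bracket string.

    ``column`` is the 0-based offending column, or the string length for an
    unmatched '(' detected at end of input.
    """

    def __init__(self, message: str, column: int | None = None):
        super().__init__(message)
        self.column = column


class RnaModelNotApplicableError(Its2DistError):
    """A partition required by the mixed RNA model has no usable sites.

    Mirrors the screening step that removes alignments with no variable
    (or no usable) stem or loop sites before paired-site analysis.
    """


class SaturationError(Its2DistError):
    """A closed-form distance is undefined (log argument <= 0)."""


class UndefinedRatioError(Its2DistError):
    """A ratio statistic has a zero denominator (e.g. SRL = 0 or GD_DNA = 0)."""
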