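"""Exception hierarchy.

Every error raised by this package derives from :class:`CCCOTError`, so a
pipeline driver can catch one type and report the offending stage.
"""


class CCCOTError(Exception):
    """Base class for all cccot errors."""


class FormatError(CCCOTError):
    """Input file does not have the expected shape (e.g. a missing column)."""


class ValidationError(CCCOTError):
    """Input parses but violates a model precondition (e.g. negative weight)."""


class ParameterError(CCCOTError):
    """A numeric parameter is outside its admissible range."""


class NumericError(CCCOTError):
    """A numerical routine failed to converge or produced an invalid value."""


class GenerationError(CCCOTError):
    """The synthetic-cohort generator cannot satisfy the requested spec."""
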