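"""Exception hierarchy for identifier generation and validation.

Every error raised by this package derives from :class:`NHashError`, so
callers can catch one base class. Input-validation failures are split into
distinct subclasses because the CLI maps them to different exit codes and
batch processing wants to report them per field.
"""


class NHashError(ValueError):
    """Base class for all errors raised by the nhash package."""


class InvalidNameError(NHashError):
    """Name contains no usable alphabetic characters after sanitization."""


class InvalidMRNError(NHashError):
    """Medical record number is not a digit string of at most 8 digits."""


class InvalidDOBError(NHashError):
    """Date of birth is missing, unparseable, or not a real calendar date."""


class InvalidCharacterError(NHashError):
    """A string contains characters outside the A-Z / 0-9 cipher alphabet."""


class MalformedIdentifierError(NHashError):
    """Identifier has the wrong length or illegal characters for a profile.

    Distinct from "well-formed but invalid": a malformed identifier cannot
    even be parsed into a cipher part and a random suffix, whereas an invalid
    one parses fine but fails regeneration against the codebook record.
    """


class RetryExhaustedError(NHashError):
    """All retry draws collided with registered identifiers.

    Signals a (locally) saturated registry for this demographic record:
    every random suffix tried already maps to a registered identifier.
    """


class ProfileMismatchError(NHashError):
    """Two registries (or an identifier and a profile) disagree on shape."""
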