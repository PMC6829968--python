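"""Exception hierarchy.

All package-specific failures derive from :class:`EmgError` so callers can
catch one base class at pipeline boundaries.
"""


class EmgError(Exception):
    """Base class for all emgsym errors."""


class FormatError(EmgError):
    """A file does not conform to the expected dialect (bad column, ragged row...)."""


class ValidationError(EmgError):
    """Metadata or annotations violate an invariant."""


class ParameterError(EmgError):
    """An operation was called with out-of-range parameters."""


class LengthError(EmgError):
    """A signal is too short for the requested operation."""


class MontageError(EmgError):
    """A required (muscle, side) channel is missing or duplicated."""


class DegenerateSignalError(EmgError):
    """The signal content makes the requested quantity undefined (e.g. all-zero session)."""


class UndefinedIndexError(EmgError):
    """An index is mathematically undefined for this input (e.g. zero-variance MCS)."""
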