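"""Exception hierarchy.

All errors raised by gradsuite derive from :class:`GradsuiteError` so callers
can catch pipeline failures without masking programming errors.
"""


class GradsuiteError(Exception):
    """Base class for all gradsuite errors."""


class FormatError(GradsuiteError):
    """A file does not conform to its declared on-disk format."""


class DialectError(FormatError):
    """A confounds table is missing columns required by its dialect."""


class ContractError(GradsuiteError):
    """An in-memory object violates a documented precondition."""


class DegenerateDataError(GradsuiteError):
    """Input is structurally valid but statistically degenerate
    (all volumes flagged, zero variance, all-zero eigenvalues, ...)."""
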