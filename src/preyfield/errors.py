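"""Exception hierarchy shared across the package.

Validation errors describe contract violations in user-supplied data
(bad values, impossible parameters); format errors describe files that
cannot be parsed into the expected table layout at all.
"""


class PreyfieldError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PreyfieldError):
    """A file does not conform to the declared dialect (missing columns, unparseable rows)."""


class ValidationError(PreyfieldError):
    """Parsed data or parameters violate a documented invariant."""
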