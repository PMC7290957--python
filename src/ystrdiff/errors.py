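"""Exception hierarchy."""


class YstrdiffError(Exception):
    """Base class for all package errors."""


class FormatError(YstrdiffError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(YstrdiffError):
    """Inputs violate a documented precondition or invariant."""
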