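"""Typed exceptions so batch pipelines can skip-and-log rather than crash."""


class MpskelError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MpskelError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class FormatError(MpskelError, ValueError):
    """A file does not conform to a supported dialect (names the offending column/row)."""


class DegenerateInputError(MpskelError, ValueError):
    """Input is structurally valid but analysis is undefined (e.g. zero-variance profile)."""


class DataError(MpskelError, ValueError):
    """Measured data violate a physical assumption (e.g. non-positive reference intensity)."""


class FitError(MpskelError, RuntimeError):
    """A model fit failed to converge; carries diagnostics in the message."""
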