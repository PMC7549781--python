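"""Package-wide exception types."""


class DdaseError(Exception):
    """Base class for all package errors."""


class ValidationError(DdaseError):
    """Malformed input: bad schema, impossible counts, unknown codes."""


class SaturationError(DdaseError):
    """All (or effectively all) droplets positive: lambda is not estimable."""


class EmptyRunError(DdaseError):
    """A well with zero accepted droplets carries no information."""
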