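"""Exception hierarchy shared across the pipeline stages."""


class CircalipidError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CircalipidError, ValueError):
    """A configuration value, profile or effect specification is invalid."""


class InsufficientDataError(CircalipidError):
    """Too few observations (insufficient df) for the requested fit."""


class DegenerateInputError(CircalipidError):
    """Input whose support cannot identify the requested quantity
    (e.g. all-missing series, time span below half a period)."""
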