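"""Exception hierarchy shared across the package."""


class DietstatError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DietstatError):
    """A value violates a documented precondition (negative weight, bad length, ...)."""


class ConfigurationError(DietstatError):
    """Malformed configuration: missing columns, unknown factor names, bad pools."""


class LinkageError(DietstatError):
    """A stomach references a station that does not exist."""


class NoDataError(DietstatError):
    """A filter or computation left no usable data; never returned silently."""
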