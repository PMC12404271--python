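"""Exception hierarchy shared across the pipeline stages."""


class IciqtlError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IciqtlError, ValueError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(IciqtlError, ValueError):
    """Input values violate a documented invariant (bad arm label, NA day, ...)."""


class ParameterError(IciqtlError, ValueError):
    """A configuration or function parameter is out of its legal range."""


class DegenerateDataError(IciqtlError, ValueError):
    """The computation is undefined on this input (e.g. zero total variance)."""


class ImputationError(IciqtlError, ValueError):
    """Slope imputation was requested in an arm with no fitted slopes."""
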