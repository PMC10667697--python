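"""Exception hierarchy for trial analysis."""


class TrialQGError(Exception):
    """Base class for all package errors."""


class FormatError(TrialQGError):
    """A file does not have the expected layout (missing columns, bad header)."""


class DataError(TrialQGError):
    """A table violates a data invariant (duplicate keys, non-numeric values)."""


class DesignError(TrialQGError):
    """The experimental layout cannot support the requested analysis."""


class DomainError(TrialQGError, ValueError):
    """A numeric argument is outside the domain of the formula."""


class SpecError(TrialQGError):
    """A synthetic-trial specification is internally inconsistent."""


class ConfigError(TrialQGError):
    """A run configuration references unknown stages or missing paths."""
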