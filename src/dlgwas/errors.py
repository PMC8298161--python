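"""Exception types shared across the pipeline."""


class DlgwasError(Exception):
    """Base class for all package errors."""


class FormatError(DlgwasError, ValueError):
    """A text input file violates the expected layout."""


class UndefinedValueError(DlgwasError, ValueError):
    """A statistic is undefined for the given input (e.g. all calls missing)."""


class SimulationError(DlgwasError, RuntimeError):
    """The simulator configuration cannot be satisfied."""


class ConfigurationError(DlgwasError, ValueError):
    """A model or pipeline configuration is inconsistent."""
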