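"""Exception hierarchy."""


class MemsoluteError(Exception):
    """Base class for all package errors."""


class FormatError(MemsoluteError):
    """Malformed or inconsistent input files (atom-count mismatch, bad box...)."""


class ConfigurationError(MemsoluteError):
    """Invalid configuration: unresolvable roles, bad parameter values."""


class AnalysisError(MemsoluteError):
    """An analysis cannot be carried out on the given data."""
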