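"""Exception types shared across the pipeline."""


class SynoliticError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynoliticError):
    """A specification or configuration value is invalid."""


class StructuralError(SynoliticError):
    """Tables or graphs that must align structurally do not."""


class LeakageError(SynoliticError):
    """A fitting routine touched rows it must not see."""
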