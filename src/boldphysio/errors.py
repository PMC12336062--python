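"""Exception hierarchy shared across the package."""


class BoldPhysioError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BoldPhysioError):
    """Invalid scenario, profile, or parameter record."""


class DataError(BoldPhysioError):
    """Input data violates a precondition (degenerate signal, grid mismatch, ...)."""


class PipelineError(BoldPhysioError):
    """Stage dependencies or outputs are inconsistent."""
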