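"""Exception types shared across the package."""


class MicrosnvError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MicrosnvError, ValueError):
    """A file violates its documented dialect (bad characters, malformed rows, ...)."""


class ConfigError(MicrosnvError, ValueError):
    """A configuration value is missing, out of range, or inconsistent."""


class AnalysisError(MicrosnvError, ValueError):
    """An operation was asked to run on input that violates its preconditions."""
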