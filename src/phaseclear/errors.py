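"""Exception hierarchy."""


class PhaseclearError(Exception):
    """Base class for all package errors."""


class ConfigError(PhaseclearError, ValueError):
    """Invalid simulation or analysis configuration; message names the field."""


class ValidationError(PhaseclearError, ValueError):
    """Invalid or inconsistent data; message names the offending object."""
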